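# Equilibrium constant set for IVT solution speciation (25 C, ideal-solution
# reference state, constants from critically evaluated stability-constant
# compilations; NTP values are ATP-like and shared across the four bases).
#
# Each species is a formation reaction from free components
#   {H, Mg, A, U, C, G, cap, Pi, PPi, tris, Ac}
# with log10 cumulative formation constant `log_beta`, net `charge`, and the
# ion-specific effective-salt weight `omega` (weighted sum over complexes
# gives the effective salt concentration governing promoter detachment).
version: "ivtkit-constants-2026.1"
log_ksp_mg3po42: -28.0   # anhydrous Mg3(PO4)2 polymorph (less soluble than hydrated forms)
species:
  - {name: "H+",        stoich: {H: 1},              log_beta: 0.0,    charge: 1,  omega: 0.0}
  - {name: "OH-",       stoich: {H: -1},             log_beta: -13.997, charge: -1, omega: 0.0}
  - {name: "Mg2+",      stoich: {Mg: 1},             log_beta: 0.0,    charge: 2,  omega: 3.0}

  - {name: "ATP4-",     stoich: {A: 1},              log_beta: 0.0,    charge: -4, omega: 2.0}
  - {name: "HATP3-",    stoich: {H: 1, A: 1},        log_beta: 6.51,   charge: -3, omega: 1.5}
  - {name: "H2ATP2-",   stoich: {H: 2, A: 1},        log_beta: 10.56,  charge: -2, omega: 1.0}
  - {name: "MgATP2-",   stoich: {Mg: 1, A: 1},       log_beta: 4.22,   charge: -2, omega: 1.0}
  - {name: "MgHATP-",   stoich: {Mg: 1, H: 1, A: 1}, log_beta: 8.83,   charge: -1, omega: 0.8}

  - {name: "UTP4-",     stoich: {U: 1},              log_beta: 0.0,    charge: -4, omega: 2.0}
  - {name: "HUTP3-",    stoich: {H: 1, U: 1},        log_beta: 6.51,   charge: -3, omega: 1.5}
  - {name: "H2UTP2-",   stoich: {H: 2, U: 1},        log_beta: 10.56,  charge: -2, omega: 1.0}
  - {name: "MgUTP2-",   stoich: {Mg: 1, U: 1},       log_beta: 4.22,   charge: -2, omega: 1.0}
  - {name: "MgHUTP-",   stoich: {Mg: 1, H: 1, U: 1}, log_beta: 8.83,   charge: -1, omega: 0.8}

  - {name: "CTP4-",     stoich: {C: 1},              log_beta: 0.0,    charge: -4, omega: 2.0}
  - {name: "HCTP3-",    stoich: {H: 1, C: 1},        log_beta: 6.51,   charge: -3, omega: 1.5}
  - {name: "H2CTP2-",   stoich: {H: 2, C: 1},        log_beta: 10.56,  charge: -2, omega: 1.0}
  - {name: "MgCTP2-",   stoich: {Mg: 1, C: 1},       log_beta: 4.22,   charge: -2, omega: 1.0}
  - {name: "MgHCTP-",   stoich: {Mg: 1, H: 1, C: 1}, log_beta: 8.83,   charge: -1, omega: 0.8}

  - {name: "GTP4-",     stoich: {G: 1},              log_beta: 0.0,    charge: -4, omega: 2.0}
  - {name: "HGTP3-",    stoich: {H: 1, G: 1},        log_beta: 6.51,   charge: -3, omega: 1.5}
  - {name: "H2GTP2-",   stoich: {H: 2, G: 1},        log_beta: 10.56,  charge: -2, omega: 1.0}
  - {name: "MgGTP2-",   stoich: {Mg: 1, G: 1},       log_beta: 4.22,   charge: -2, omega: 1.0}
  - {name: "MgHGTP-",   stoich: {Mg: 1, H: 1, G: 1}, log_beta: 8.83,   charge: -1, omega: 0.8}

  # AG trinucleoside cap analog: triphosphate-bridged, treated NTP-like for
  # protonation/Mg binding; omega matches an NTP (main-text gap, configurable)
  - {name: "cap4-",     stoich: {cap: 1},              log_beta: 0.0,   charge: -4, omega: 2.0}
  - {name: "Hcap3-",    stoich: {H: 1, cap: 1},        log_beta: 6.51,  charge: -3, omega: 1.5}
  - {name: "H2cap2-",   stoich: {H: 2, cap: 1},        log_beta: 10.56, charge: -2, omega: 1.0}
  - {name: "Mgcap2-",   stoich: {Mg: 1, cap: 1},       log_beta: 4.22,  charge: -2, omega: 1.0}
  - {name: "MgHcap-",   stoich: {Mg: 1, H: 1, cap: 1}, log_beta: 8.83,  charge: -1, omega: 0.8}

  - {name: "PO43-",     stoich: {Pi: 1},               log_beta: 0.0,    charge: -3, omega: 1.5}
  - {name: "HPO42-",    stoich: {H: 1, Pi: 1},         log_beta: 12.375, charge: -2, omega: 1.0}
  - {name: "H2PO4-",    stoich: {H: 2, Pi: 1},         log_beta: 19.573, charge: -1, omega: 0.6}
  - {name: "H3PO4",     stoich: {H: 3, Pi: 1},         log_beta: 21.721, charge: 0,  omega: 0.0}
  - {name: "MgHPO4",    stoich: {Mg: 1, H: 1, Pi: 1},  log_beta: 15.085, charge: 0,  omega: 0.0}

  - {name: "PPi4-",     stoich: {PPi: 1},              log_beta: 0.0,   charge: -4, omega: 2.0}
  - {name: "HPPi3-",    stoich: {H: 1, PPi: 1},        log_beta: 9.40,  charge: -3, omega: 1.5}
  - {name: "H2PPi2-",   stoich: {H: 2, PPi: 1},        log_beta: 16.08, charge: -2, omega: 1.0}
  - {name: "MgPPi2-",   stoich: {Mg: 1, PPi: 1},       log_beta: 5.42,  charge: -2, omega: 1.0}

  - {name: "tris",      stoich: {tris: 1},             log_beta: 0.0,   charge: 0,  omega: 0.0}
  - {name: "trisH+",    stoich: {H: 1, tris: 1},       log_beta: 8.07,  charge: 1,  omega: 0.6}

  - {name: "Ac-",       stoich: {Ac: 1},               log_beta: 0.0,   charge: -1, omega: 0.4}
  - {name: "HAc",       stoich: {H: 1, Ac: 1},         log_beta: 4.757, charge: 0,  omega: 0.0}

# Spectator species carried outside the equilibrium solve: monovalent
# counterions and the RNA backbone phosphodiesters (condensed counterions,
# no free-salt contribution by default).
inert_species:
  - {name: "Na+",           charge: 1,  omega: 1.0}
  - {name: "Cl-",           charge: -1, omega: 1.0}
  - {name: "strong_base+",  charge: 1,  omega: 1.0}
  - {name: "RNA_backbone-", charge: -1, omega: 0.0}
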