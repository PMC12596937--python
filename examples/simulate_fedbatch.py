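"""Heuristic versus model-optimized fed-batch transcription.

Simulates the bundled reconstructions of a conventional 5 mM-setpoint
protocol (chloride-heavy buffer, open-loop feeding) and the model-based
2 mM-setpoint protocol (tris-base buffer, predictive feeding, end-of-run pH
relaxation), both on the salt-sensitive construct, and prints the outcome.
"""

from ivtkit.scenarios import make_scenarios

bundle = make_scenarios(seed=0)

for name in ("heuristic_fedbatch", "optimized_fedbatch_lowpH"):
    res = bundle.simulate(name)
    s = res.summary()
    print(f"\n{name}")
    print(f"  final RNA        {s['final_RNA_M'] * 1e6:.2f} uM "
          f"({s['final_RNA_gL']:.1f} g/L)")
    print(f"  effective salt   {res.effective_salt[0] * 1e3:.0f} -> "
          f"{s['final_effective_salt_mM']:.0f} mM")
    print(f"  final pH         {s['final_pH']:.2f}")
    print(f"  residual rate    {res.rate[-1] / res.rate[0] * 100:.1f}% of initial")

heur = bundle.simulate("heuristic_fedbatch").rna_molar[-1]
opt = bundle.simulate("optimized_fedbatch_lowpH").rna_molar[-1]
print(f"\noptimized / heuristic RNA yield: {opt / heur:.2f}x")
# The heuristic run accumulates >400 mM effective salt and stalls near
# 3.5 uM RNA; the optimized run keeps salt low enough to pass 7 uM while
# retaining roughly a third of its initial rate.
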