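"""Configuration parsing, validation and serialization.

All user-facing files are YAML (recipes, policies, parameters, objectives)
or CSV (tabular data); concentrations are millimolar at every interface and
converted to SI molar internally.  Parsing is strict: unknown keys raise a
:class:`ValidationError` naming the key and file, and referenced files are
validated before any computation starts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .capping import CappingParameters
from .errors import ValidationError
from .estimation import CFMeasurement
from .kinetics import CatalystState, KineticParameters
from .reactor import ContinuousFeed, FeedEvent, FeedPolicy
from .speciation import NTP_BASES, SolutionComposition

__all__ = [
    "RunConfig",
    "load_recipe",
    "recipe_to_dict",
    "load_policy",
    "save_policy",
    "load_kinetic_parameters",
    "load_capping_parameters",
    "save_capping_parameters",
    "load_measurements_csv",
    "load_and_validate",
    "write_provenance",
]

_RECIPE_KEYS = {
    "Mg_mM": "total_Mg",
    "NTP_A_mM": ("total_NTP", "A"),
    "NTP_U_mM": ("total_NTP", "U"),
    "NTP_C_mM": ("total_NTP", "C"),
    "NTP_G_mM": ("total_NTP", "G"),
    "cap_mM": "total_cap_analog",
    "phosphate_mM": "total_phosphate",
    "pyrophosphate_mM": "total_pyrophosphate",
    "tris_mM": "total_tris",
    "acetate_mM": "total_acetate",
    "sodium_mM": "sodium",
    "chloride_mM": "chloride",
    "strong_base_mM": "strong_base_equivalents",
    "rna_backbone_mM": "rna_phosphodiester",
}


def _check_keys(mapping, allowed, context):
    if not isinstance(mapping, dict):
        raise ValidationError(f"{context}: expected a mapping")
    unknown = set(mapping) - set(allowed)
    if unknown:
        raise ValidationError(
            f"{context}: unknown key(s) {sorted(unknown)}; allowed: {sorted(allowed)}"
        )


def _as_mapping(doc, context):
    if not isinstance(doc, dict):
        raise ValidationError(f"{context}: file does not contain a mapping")
    return doc


def recipe_from_mapping(doc: dict, context: str = "recipe") -> SolutionComposition:
    allowed = set(_RECIPE_KEYS) | {"temperature_K"}
    _check_keys(doc, allowed, context)
    kwargs: dict = {"total_NTP": {b: 0.0 for b in NTP_BASES}}
    for key, value in doc.items():
        if key == "temperature_K":
            kwargs["temperature"] = float(value)
            continue
        field = _RECIPE_KEYS[key]
        molar = float(value) * 1e-3
        if isinstance(field, tuple):
            kwargs["total_NTP"][field[1]] = molar
        else:
            kwargs[field] = molar
    return SolutionComposition(**kwargs)


def recipe_to_dict(comp: SolutionComposition) -> dict:
    out = {}
    for key, field in _RECIPE_KEYS.items():
        if isinstance(field, tuple):
            v = comp.total_NTP[field[1]]
        else:
            v = getattr(comp, field)
        if v != 0.0:
            out[key] = round(float(v) * 1e3, 9)
    if comp.temperature != 298.15:
        out["temperature_K"] = float(comp.temperature)
    return out


def load_recipe(path) -> SolutionComposition:
    doc = _as_mapping(yaml.safe_load(Path(path).read_text()), str(path))
    return recipe_from_mapping(doc, context=str(path))


# ---------------------------------------------------------------------------
# feed policies

_POLICY_KEYS = {
    "name", "initial_volume_L", "t_final_s", "catalysts", "initial_recipe",
    "events", "continuous",
}
_EVENT_KEYS = {"time_s", "volume_uL", "recipe", "label"}
_CATALYST_KEYS = {"dna_nM", "polymerase_nM"}
_CONTINUOUS_KEYS = {"recipe", "segments"}
_SEGMENT_KEYS = {"t_start_s", "t_end_s", "rate_uL_per_min"}


def policy_from_mapping(doc: dict, context: str = "policy") -> FeedPolicy:
    _check_keys(doc, _POLICY_KEYS, context)
    for req in ("initial_volume_L", "t_final_s", "catalysts", "initial_recipe"):
        if req not in doc:
            raise ValidationError(f"{context}: missing required key {req!r}")
    cat = doc["catalysts"]
    _check_keys(cat, _CATALYST_KEYS, f"{context}.catalysts")
    catalysts = CatalystState(
        dna=float(cat.get("dna_nM", 0.0)) * 1e-9,
        polymerase=float(cat.get("polymerase_nM", 0.0)) * 1e-9,
    )
    events = []
    for i, ev in enumerate(doc.get("events") or []):
        _check_keys(ev, _EVENT_KEYS, f"{context}.events[{i}]")
        events.append(
            FeedEvent(
                time=float(ev["time_s"]),
                volume=float(ev["volume_uL"]) * 1e-6,
                composition=recipe_from_mapping(
                    ev["recipe"], f"{context}.events[{i}].recipe"
                ),
                label=str(ev.get("label", "")),
            )
        )
    continuous = None
    if doc.get("continuous") is not None:
        c = doc["continuous"]
        _check_keys(c, _CONTINUOUS_KEYS, f"{context}.continuous")
        segs = []
        for i, s in enumerate(c.get("segments") or []):
            _check_keys(s, _SEGMENT_KEYS, f"{context}.continuous.segments[{i}]")
            segs.append(
                (
                    float(s["t_start_s"]),
                    float(s["t_end_s"]),
                    float(s["rate_uL_per_min"]) * 1e-6 / 60.0,
                )
            )
        continuous = ContinuousFeed(
            composition=recipe_from_mapping(
                c["recipe"], f"{context}.continuous.recipe"
            ),
            segments=tuple(segs),
        )
    return FeedPolicy(
        initial_composition=recipe_from_mapping(
            doc["initial_recipe"], f"{context}.initial_recipe"
        ),
        initial_volume=float(doc["initial_volume_L"]),
        catalysts=catalysts,
        events=tuple(events),
        continuous=continuous,
        t_final=float(doc["t_final_s"]),
        name=str(doc.get("name", "")),
    )


def policy_to_mapping(policy: FeedPolicy) -> dict:
    doc: dict = {
        "name": policy.name,
        "initial_volume_L": float(policy.initial_volume),
        "t_final_s": float(policy.t_final),
        "catalysts": {
            "dna_nM": round(float(policy.catalysts.dna) * 1e9, 9),
            "polymerase_nM": round(float(policy.catalysts.polymerase) * 1e9, 9),
        },
        "initial_recipe": recipe_to_dict(policy.initial_composition),
    }
    if policy.events:
        doc["events"] = [
            {
                "time_s": float(ev.time),
                "volume_uL": round(float(ev.volume) * 1e6, 9),
                "label": ev.label,
                "recipe": recipe_to_dict(ev.composition),
            }
            for ev in policy.events
        ]
    if policy.continuous is not None:
        doc["continuous"] = {
            "recipe": recipe_to_dict(policy.continuous.composition),
            "segments": [
                {
                    "t_start_s": float(t0),
                    "t_end_s": float(t1),
                    "rate_uL_per_min": round(float(q) * 60.0 * 1e6, 9),
                }
                for t0, t1, q in policy.continuous.segments
            ],
        }
    return doc


def load_policy(path) -> FeedPolicy:
    doc = _as_mapping(yaml.safe_load(Path(path).read_text()), str(path))
    return policy_from_mapping(doc, context=str(path))


def save_policy(policy: FeedPolicy, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(policy_to_mapping(policy), sort_keys=True)
    )


# ---------------------------------------------------------------------------
# parameters

_KINETIC_KEYS = {
    "log10_k_off_1M", "k_off_1M", "n_salt", "k_on", "k_cat", "K_M_mgntp_mM",
    "K_a", "K_b", "extra_proton_stoich",
}


def load_kinetic_parameters(path) -> KineticParameters:
    doc = _as_mapping(yaml.safe_load(Path(path).read_text()), str(path))
    _check_keys(doc, _KINETIC_KEYS, str(path))
    if "log10_k_off_1M" in doc and "k_off_1M" in doc:
        raise ValidationError(f"{path}: give k_off_1M or its log10, not both")
    kwargs = {}
    if "log10_k_off_1M" in doc:
        kwargs["k_off_1M"] = 10.0 ** float(doc["log10_k_off_1M"])
    if "k_off_1M" in doc:
        kwargs["k_off_1M"] = float(doc["k_off_1M"])
    if "K_M_mgntp_mM" in doc:
        kwargs["K_M_mgntp"] = float(doc["K_M_mgntp_mM"]) * 1e-3
    for key in ("n_salt", "k_on", "k_cat", "K_a", "K_b", "extra_proton_stoich"):
        if key in doc:
            kwargs[key] = float(doc[key])
    return KineticParameters(**kwargs)


def load_capping_parameters(path) -> CappingParameters:
    doc = _as_mapping(
        json.loads(Path(path).read_text())
        if str(path).endswith(".json")
        else yaml.safe_load(Path(path).read_text()),
        str(path),
    )
    _check_keys(doc, {"lambda_per_M", "theta_mM", "covariance"}, str(path))
    cov = np.asarray(doc.get("covariance", [[0, 0], [0, 0]]), dtype=float)
    return CappingParameters(
        lam=float(doc["lambda_per_M"]),
        theta=float(doc["theta_mM"]) * 1e-3,
        covariance=cov,
    )


def save_capping_parameters(params: CappingParameters, path) -> None:
    doc = {
        "lambda_per_M": params.lam,
        "theta_mM": params.theta * 1e3,
        "covariance": np.asarray(params.covariance).tolist(),
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def load_measurements_csv(path) -> list[CFMeasurement]:
    """Calibration table: columns ATP_mM, GTP_mM, cap_mM, CF_measured, CF_sd."""
    df = pd.read_csv(path)
    required = {"ATP_mM", "GTP_mM", "cap_mM", "CF_measured", "CF_sd"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return [
        CFMeasurement(
            atp=row.ATP_mM * 1e-3, gtp=row.GTP_mM * 1e-3, cap=row.cap_mM * 1e-3,
            cf=row.CF_measured, sd=row.CF_sd,
        )
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# run configuration and provenance

_RUN_KEYS = {
    "policy", "recipe", "kinetic_parameters", "capping_parameters",
    "output_dir", "seed", "rtol", "report_interval_s", "verbosity",
}


@dataclass(frozen=True)
class RunConfig:
    policy: Path | None = None
    recipe: Path | None = None
    kinetic_parameters: Path | None = None
    capping_parameters: Path | None = None
    output_dir: Path = Path("results")
    seed: int = 0
    rtol: float = 1e-8
    report_interval_s: float = 60.0
    verbosity: str = "info"


def load_and_validate(path) -> RunConfig:
    """Load a run configuration, checking keys and file existence up front."""
    doc = _as_mapping(yaml.safe_load(Path(path).read_text()), str(path))
    _check_keys(doc, _RUN_KEYS, str(path))
    kwargs: dict = {}
    for key in ("policy", "recipe", "kinetic_parameters", "capping_parameters"):
        if doc.get(key) is not None:
            p = Path(doc[key])
            if not p.exists():
                raise ValidationError(f"{path}: referenced file {p} does not exist")
            kwargs[key] = p
    if "output_dir" in doc:
        kwargs["output_dir"] = Path(doc["output_dir"])
    for key, cast in (("seed", int), ("rtol", float),
                      ("report_interval_s", float), ("verbosity", str)):
        if key in doc:
            kwargs[key] = cast(doc[key])
    cfg = RunConfig(**kwargs)
    # eager schema validation of referenced files
    if cfg.policy:
        load_policy(cfg.policy)
    if cfg.recipe:
        load_recipe(cfg.recipe)
    if cfg.kinetic_parameters:
        load_kinetic_parameters(cfg.kinetic_parameters)
    if cfg.capping_parameters:
        load_capping_parameters(cfg.capping_parameters)
    return cfg


def write_provenance(out_dir, *, command: str, seed: int | None,
                     inputs: dict[str, Path]) -> None:
    """Record seed, input-file hashes and package version for a run."""
    rec = {
        "command": command,
        "seed": seed,
        "package_version": __version__,
        "input_sha256": {
            name: hashlib.sha256(Path(p).read_bytes()).hexdigest()
            for name, p in inputs.items()
            if p is not None and Path(p).exists()
        },
    }
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "provenance.json").write_text(json.dumps(rec, indent=2, sort_keys=True) + "\n")
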