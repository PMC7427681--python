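"""End-to-end workflow driver: phantom cohort -> dose maps -> DVH -> agreement.

Reproduces the study workflow on synthetic data: generate a cohort of
digital-liver phantoms, propagate and (optionally) relocate the tumor
VOIs on each activity grid, normalize the pre-treatment map per perfusion
territory and the post-treatment map to the administered activity, convert
to dose with the local-deposition S value of each grid, extract DVH
parameters per compartment, and feed the paired predicted/measured values
into the statistical agreement layer.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignment import AlignmentProblem, optimize_location
from .comparison import PairedSeries, agreement_report, classify_criteria
from .dosimetry import DoseKernel, dose_map, normalize_post, normalize_pre
from .dvh import compartment_report
from .phantom import PhantomSpec, TumorSpec, build_phantom
from .volumes import CompartmentSet, VOIMask, resample_mask

__all__ = ["RunConfig", "load_config", "run_pipeline"]


@dataclass
class RunConfig:
    """Validated configuration for a phantom-driven pipeline run."""

    seed: int = 0
    n_phantoms: int = 1
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    align: bool = True
    beta: float = 1.0
    max_shift_mm: float = 15.0
    fuzzy_threshold: float = 0.5
    # per-replicate randomization of the controlled imperfections
    discrepancy_sigma: float = 0.0     # lognormal sigma on tumor discrepancy
    misalignment_max_mm: float = 0.0   # uniform-in-ball tumor mask shift

    def __post_init__(self) -> None:
        if self.n_phantoms < 1:
            raise ValueError("n_phantoms must be >= 1")
        if self.discrepancy_sigma < 0 or self.misalignment_max_mm < 0:
            raise ValueError("randomization magnitudes must be >= 0")
        if not 0 < self.fuzzy_threshold < 1:
            raise ValueError("fuzzy_threshold must lie in (0, 1)")


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    phantom_raw = raw.pop("phantom", {})
    tumors_raw = phantom_raw.pop("tumors", None)
    kwargs = dict(phantom_raw)
    if tumors_raw is not None:
        kwargs["tumors"] = tuple(
            TumorSpec(**{**t, "center_mm": tuple(t["center_mm"]),
                         "misalignment_mm": tuple(t.get("misalignment_mm", (0, 0, 0)))})
            for t in tumors_raw
        )
    for key in ("liver_center_mm", "liver_semiaxes_mm", "pre_spacing_mm",
                "post_spacing_mm", "administered_gbq"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    spec = PhantomSpec(**kwargs)
    return RunConfig(phantom=spec, **raw)


def _randomized_spec(cfg: RunConfig, replicate: int, rng: np.random.Generator) -> PhantomSpec:
    tumors = []
    for t in cfg.phantom.tumors:
        disc, mis = t.discrepancy, t.misalignment_mm
        if cfg.discrepancy_sigma > 0:
            disc = float(np.exp(rng.normal(0.0, cfg.discrepancy_sigma)))
        if cfg.misalignment_max_mm > 0:
            v = rng.standard_normal(3)
            v /= max(np.linalg.norm(v), 1e-12)
            mis = tuple(v * cfg.misalignment_max_mm * rng.uniform() ** (1 / 3))
        tumors.append(replace(t, discrepancy=disc, misalignment_mm=mis))
    return replace(cfg.phantom, seed=int(cfg.seed + replicate), tumors=tuple(tumors))


def _session_compartments(phantom, session: str, cfg: RunConfig):
    """Resample masks onto a session's activity grid, optionally relocating tumors."""
    activity = phantom.pre if session == "pre" else phantom.post
    grid = activity.grid
    thr = cfg.fuzzy_threshold
    liver = resample_mask(phantom.compartments.liver, grid).threshold(thr)
    lpts = [resample_mask(m, grid).threshold(thr) for m in phantom.compartments.lpts]
    tumors, shifts = [], []
    for t in phantom.compartments.tumors:
        if cfg.align and not t.is_empty:
            # relocate the mask at its native (fine) resolution
            problem = AlignmentProblem(t, activity, beta=cfg.beta,
                                       max_shift_mm=cfg.max_shift_mm,
                                       fuzzy_threshold=thr)
            res = optimize_location(problem)
            relocated = res.final
            shifts.append(res.shift_mm)
        else:
            relocated = t
            shifts.append(np.zeros(3))
        coarse = resample_mask(relocated, grid).threshold(thr)
        tumors.append(VOIMask(grid, coarse.membership, t.label))
    comp = CompartmentSet.assemble(liver, lpts, tumors, warn_uncovered=False)
    return comp, shifts


def _session_dose(phantom, session: str, comp: CompartmentSet, kernel: DoseKernel):
    activity = phantom.pre if session == "pre" else phantom.post
    spec = phantom.spec
    if session == "pre":
        normalized = normalize_pre(activity, comp.lpts, list(spec.administered_gbq))
    else:
        normalized = normalize_post(activity, comp.liver, float(sum(spec.administered_gbq)))
    return dose_map(normalized, kernel.s_value(activity.grid))


def run_pipeline(cfg: RunConfig, out_dir=None) -> dict:
    """Run the full phantom-cohort workflow; optionally write the report bundle.

    Returns a dict with the per-VOI DVH table (both sessions, all
    replicates), the paired mean-dose series, agreement statistics and
    fixed-dose-criteria classifications.  Deterministic for a fixed config.
    """
    rng = np.random.default_rng(cfg.seed)
    kernel = DoseKernel()
    tables = []
    pairs: dict[str, dict[str, list]] = {
        "tumor": {"labels": [], "pre": [], "post": []},
        "ntv": {"labels": [], "pre": [], "post": []},
        "lpt": {"labels": [], "pre": [], "post": []},
    }

    for rep in range(cfg.n_phantoms):
        spec = _randomized_spec(cfg, rep, rng)
        phantom = build_phantom(spec)
        per_session = {}
        for session in ("pre", "post"):
            comp, shifts = _session_compartments(phantom, session, cfg)
            dose = _session_dose(phantom, session, comp, kernel)
            table, _ = compartment_report(dose, comp)
            table.insert(0, "session", session)
            table.insert(0, "replicate", rep)
            tables.append(table)
            per_session[session] = table.set_index("voi")
        for kind, key_prefix in (("tumor", "tumor"), ("ntv-total", "ntv"), ("lpt", "lpt")):
            pre_t = per_session["pre"]
            post_t = per_session["post"]
            for voi in pre_t.index[pre_t["kind"] == kind]:
                if voi not in post_t.index:
                    continue
                bucket = pairs[key_prefix]
                bucket["labels"].append(f"rep{rep}:{voi}")
                bucket["pre"].append(float(pre_t.loc[voi, "mean_gy"]))
                bucket["post"].append(float(post_t.loc[voi, "mean_gy"]))

    dvh_table = pd.concat(tables, ignore_index=True)
    result: dict = {"config": dataclasses.asdict(cfg), "version": __version__,
                    "dvh": dvh_table, "series": {}, "agreement": {},
                    "classification": {}}

    for name, compartment in (("tumor", "tumor"), ("ntv", "ntv")):
        bucket = pairs[name]
        if not bucket["labels"]:
            continue
        series = PairedSeries(np.array(bucket["pre"]), np.array(bucket["post"]),
                              labels=bucket["labels"],
                              parameter=f"{name} mean dose", units="Gy")
        result["series"][name] = series
        if series.n >= 3 and np.ptp(series.x) > 0:
            result["agreement"][name] = agreement_report(series)
        cls = classify_criteria(series, compartment)
        result["classification"][name] = {
            "region_counts": cls.region_counts,
            "joint_histogram": cls.joint_histogram.tolist(),
            "categories": dict(zip(series.labels, cls.categories)),
        }

    if out_dir is not None:
        _write_bundle(result, cfg, out_dir)
    return result


def _write_bundle(result: dict, cfg: RunConfig, out_dir) -> None:
    from .io import write_report

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result["dvh"].to_csv(out / "dvh_parameters.csv", index=False, float_format="%.6g")
    report = {k: result[k] for k in ("agreement", "classification")}
    write_report(report, out / "agreement.json")
    for name, series in result["series"].items():
        pd.DataFrame({"unit": series.labels, "predicted_gy": series.x,
                      "measured_gy": series.y}).to_csv(
            out / f"paired_{name}_mean_dose.csv", index=False, float_format="%.6g")
    provenance = {
        "config": dataclasses.asdict(cfg),
        "package_version": __version__,
        "numpy_version": np.__version__,
        "seed": cfg.seed,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))
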