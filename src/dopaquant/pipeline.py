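"""End-to-end case pipeline and machine-readable reporting.

One call takes co-registered atlas-space PET + FLAIR + labels, lateralizes
the lesion from FLAIR, extracts the data-driven normal-tissue and striatal
references from the contralateral hemisphere, finds the dual lesion maxima,
applies the selection rule and emits the two uptake ratios with full
provenance (masks, constants, decisions). Internal consistency invariants
are asserted on every run.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List

import numpy as np

from .config import PipelineConfig
from .hemisphere import (ClassifierModel, HemisphereDecision,
                         classify_and_lateralize, compute_district_features,
                         parcellate)
from .image import AtlasLabels, VolumetricImage, check_alignment, write_volume
from .maxima import (LocalMaximum, SelectedMaximum, build_complement,
                     inflate_striatal_mask, local_mean_maximum,
                     select_representative)
from .reference import ReferenceResult, extract_references
from .scoring import ScorePair, compute_scores

REPORT_NAME = "report.json"


@dataclass
class CaseResult:
    """Complete outcome of one case run."""

    c_n: float
    c_s: float
    m_in: LocalMaximum
    m_out: LocalMaximum
    selected: SelectedMaximum
    scores: ScorePair
    decision: HemisphereDecision
    masks: Dict[str, np.ndarray]
    config: PipelineConfig
    flags: List[str] = field(default_factory=list)
    log: List[str] = field(default_factory=list)
    diagnostics: Dict = field(default_factory=dict)

    @property
    def t_n(self) -> float:
        return self.scores.t_n

    @property
    def t_s(self) -> float:
        return self.scores.t_s


def _assert_invariants(result: CaseResult, pet: VolumetricImage) -> None:
    m = result.masks
    if (m["M_n"] & m["M_s"]).any():
        raise AssertionError("M_n and M_s overlap")
    if (m["M_c_s"] & m["M_c_n"]).any():
        raise AssertionError("M_c,s and M_c,n overlap")
    if not np.array_equal(m["M_c_s"] | m["M_c_n"], m["M_c"]):
        raise AssertionError("M_c,s and M_c,n do not partition M_c")
    p_n_mean = float((pet.grid[m["M_n"]] / result.c_n).mean())
    if abs(p_n_mean - 1.0) > 1e-9:
        raise AssertionError("mean of normalized PET over M_n is not 1")
    lhs, rhs = result.t_n / result.t_s, result.c_s / result.c_n
    if abs(lhs - rhs) > 1e-9 * abs(rhs):
        raise AssertionError("score identity t_n/t_s = c_s/c_n violated")


def run_case(pet: VolumetricImage, flair: VolumetricImage,
             atlas: AtlasLabels, model: ClassifierModel,
             cfg: PipelineConfig) -> CaseResult:
    """Run the full semi-quantification on one co-registered case."""
    t0 = time.perf_counter()
    log: List[str] = []
    check_alignment(pet, flair, atlas)

    brain = atlas.brain_mask()
    hemis = atlas.hemisphere_mask("left") | atlas.hemisphere_mask("right")

    districts = parcellate(flair, hemis, cfg)
    compute_district_features(districts, flair)
    log.append(f"parcellation: {len(districts)} districts")
    decision = classify_and_lateralize(model, districts, atlas)
    affected = decision.affected_side
    unaffected = "left" if affected == "right" else "right"
    log.append(
        f"affected hemisphere: {affected} "
        f"(overlap {decision.overlap_fractions[affected]:.3f})")

    ref: ReferenceResult = extract_references(pet, atlas, unaffected, cfg)
    log.append(
        f"reference: |M_n|={int(ref.m_n.sum())} c_n={ref.c_n:.6g} "
        f"|M_s|={int(ref.m_s.sum())} c_s={ref.c_s:.6g} "
        f"thresholds={['%.4g' % t for t in ref.thresholds]}")

    m_c = build_complement(brain, ref.m_n, ref.m_s)
    affected_hemi = atlas.hemisphere_mask(affected)
    from .reference import striatal_component
    seed, seed_flags = striatal_component(
        pet.grid, ref.rejected, atlas.striatum_mask(affected),
        affected_hemi, ref.c_n)
    m_c_s, grow_flags = inflate_striatal_mask(
        pet.grid, atlas.striatum_mask(affected), seed,
        m_c & affected_hemi, cfg.rho_grow, cfg.grow_max_iter)
    m_c_n = m_c & ~m_c_s
    log.append(f"complement: |M_c|={int(m_c.sum())} "
               f"|M_c,s|={int(m_c_s.sum())} |M_c,n|={int(m_c_n.sum())}")

    m_in = local_mean_maximum(pet, m_c_s, cfg.l_max)
    m_out = local_mean_maximum(pet, m_c_n, cfg.l_max)
    selected = select_representative(m_in, m_out, cfg.infiltration_assumed)
    log.append(f"m_in={m_in.value:.6g} at {m_in.center_voxel}; "
               f"m_out={m_out.value:.6g} at {m_out.center_voxel}; "
               f"selected {selected.source} ({selected.reason})")

    scores = compute_scores(selected.value, ref.c_n, ref.c_s)

    flags = list(dict.fromkeys(
        ref.flags + seed_flags + grow_flags + selected.flags))
    result = CaseResult(
        c_n=ref.c_n, c_s=ref.c_s, m_in=m_in, m_out=m_out,
        selected=selected, scores=scores, decision=decision,
        masks={
            "V_t": decision.v_t,
            **{f"M_{i + 1}": m for i, m in enumerate(ref.lobe_masks)},
            "M_n": ref.m_n, "M_s": ref.m_s,
            "M_c": m_c, "M_c_s": m_c_s, "M_c_n": m_c_n,
        },
        config=cfg, flags=flags, log=log,
        diagnostics={**ref.diagnostics,
                     "runtime_s": time.perf_counter() - t0})
    _assert_invariants(result, pet)
    return result


def _maximum_dict(m: LocalMaximum) -> Dict:
    return {
        "value": m.value,
        "voxel": list(m.center_voxel),
        "world_mm": [float(x) for x in m.center_world_mm],
        "window_half": m.window_half,
    }


def report_dict(result: CaseResult) -> Dict:
    """JSON-serializable report. Scores appear rounded to 3 decimals (the
    clinical precision) and at full precision for lossless round-trips."""
    flags = list(result.flags)
    if (result.selected.source == "m_in"
            and not result.config.infiltration_assumed):
        if "clinician review required" not in flags:
            flags.append("clinician review required")
    return {
        "t_n": round(result.t_n, 3),
        "t_s": round(result.t_s, 3),
        "scores_full": {"t_n": result.t_n, "t_s": result.t_s},
        "c_n": result.c_n,
        "c_s": result.c_s,
        "m_in": _maximum_dict(result.m_in),
        "m_out": _maximum_dict(result.m_out),
        "selected": {"source": result.selected.source,
                     "value": result.selected.value,
                     "reason": result.selected.reason},
        "affected_hemisphere": result.decision.affected_side,
        "overlap_fractions": result.decision.overlap_fractions,
        "mask_voxels": {k: int(v.sum()) for k, v in result.masks.items()},
        "flags": flags,
        "log": result.log,
        "config": result.config.to_dict(),
        "diagnostics": {"per_lobe": result.diagnostics.get("per_lobe")},
    }


def write_report(result: CaseResult, out_dir: str | Path,
                 affine: np.ndarray | None = None,
                 write_masks: bool = True) -> Path:
    """Write report.json (and the named masks as NIfTI) into out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / REPORT_NAME
    with open(path, "w") as fh:
        json.dump(report_dict(result), fh, indent=2, sort_keys=True)
    if write_masks:
        aff = affine if affine is not None else np.eye(4)
        for name, mask in result.masks.items():
            write_volume(mask, aff, out / f"{name}.nii.gz")
    return path
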