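"""End-to-end analysis pipeline and report bundle.

Runs the full study flow on one cohort: inclusion/exclusion accounting,
femoral-head coverage, Procrustes alignment, shape-model fit, per-hip
mode Z-scores, outcome derivation, the logistic association suite, an
optional reliability study from simulated re-annotations, and the export
of synthesized shapes at -2.5 / 0 / +2.5 SD per retained mode. All
products are CSV tables plus a YAML manifest recording the
configuration, seed, completed stages, and a checksum per output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from . import shape_model as sm_mod
from . import stats as hstats
from .geometry import fhc_percent
from .shape_model import AlignmentConfig
from .synthetic import SyntheticConfig, reannotate, sample_cohort

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "percent_of"]

log = logging.getLogger("hipssm")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    With ``landmarks_path``/``metadata_path`` unset, a synthetic cohort
    is generated from ``synthetic`` (its seed is overridden by ``seed``).
    """

    out_dir: str = "hipssm_out"
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    landmarks_path: Optional[str] = None
    metadata_path: Optional[str] = None
    alignment: AlignmentConfig = field(default_factory=AlignmentConfig)
    retention: float = 0.95
    ai_threshold: float = 21.0  # degrees; residual dysplasia is AI > threshold
    reliability_fraction: float = 0.2
    run_reliability: bool = True
    verbose: bool = False

    def __post_init__(self):
        if not 0.0 < self.retention <= 1.0:
            raise ValueError("retention must be in (0, 1]")
        if self.ai_threshold <= 0:
            raise ValueError("AI threshold must be positive")


def percent_of(count: int, total: int) -> int:
    """Integer percentage, rounded half away from zero (12/92 -> 13)."""
    return int(math.floor(100.0 * count / total + 0.5))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, **kwargs) -> Path:
    df.to_csv(path, float_format="%.10g", **kwargs)
    return path


def _characteristics(records, fhc_df: pd.DataFrame) -> pd.DataFrame:
    n = len(records)
    ages = np.array([r.age_at_us for r in records])
    rows = [
        ("n", f"{n}"),
        ("female", f"{sum(r.sex == 'F' for r in records)} ({percent_of(sum(r.sex == 'F' for r in records), n)})"),
        ("age_at_us_months", f"{ages.mean():.1f} ± {ages.std(ddof=1):.1f}"),
        ("graf_d", f"{sum(r.graf_type == 'D' for r in records)} ({percent_of(sum(r.graf_type == 'D' for r in records), n)})"),
        (
            "fhc_percent",
            f"{fhc_df['fhc_percent'].mean():.0f} ± {fhc_df['fhc_percent'].std(ddof=1):.0f}",
        ),
    ]
    return pd.DataFrame(rows, columns=["characteristic", "value"])


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Returns the manifest dictionary (also written to ``manifest.yaml``).
    A stage failure is recorded with the stage name and downstream
    stages are skipped.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": int(config.seed),
        "retention": float(config.retention),
        "ai_threshold": float(config.ai_threshold),
        "alignment": config.alignment.as_dict(),
        "stages": [],
        "errors": [],
        "files": {},
    }
    files: list[Path] = []
    stage = "setup"
    try:
        # ---- cohort -----------------------------------------------------
        stage = "cohort"
        if config.landmarks_path:
            hips = hio.read_landmarks(config.landmarks_path, dialect="csv")
            records = hio.read_cohort(config.metadata_path)
            truth = None
        else:
            syn = dataclasses.replace(config.synthetic, seed=int(config.seed))
            manifest["synthetic"] = {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(syn).items()
                if k != "template"
            }
            hips, records, truth = sample_cohort(syn)
        manifest["stages"].append(stage)
        log.info("cohort: %d hips", len(hips))

        # ---- inclusion flow --------------------------------------------
        stage = "inclusion"
        included, tally = hio.apply_inclusion_flow(records)
        flow = pd.DataFrame(
            [("retrieved", len(records))]
            + [(k, v) for k, v in tally.items()]
            + [("included", len(included))],
            columns=["step", "count"],
        )
        files.append(_write(flow, out / "inclusion_flow.csv", index=False))
        ids = {r.hip_id for r in included}
        hips = [h for h in hips if h.hip_id in ids]
        manifest["stages"].append(stage)

        # ---- femoral head coverage -------------------------------------
        stage = "fhc"
        fhc_rows = []
        for h in hips:
            pts = h.contour_array()
            if h.has_head:
                res = fhc_percent(
                    pts[0], pts[4], h.head_center.as_array(), h.head_rim.as_array(), pts[12]
                )
                fhc_rows.append((h.hip_id, res.percent, res.morin_category))
            else:
                fhc_rows.append((h.hip_id, np.nan, np.nan))
        fhc_df = pd.DataFrame(
            fhc_rows, columns=["hip_id", "fhc_percent", "morin_category"]
        ).set_index("hip_id")
        files.append(_write(fhc_df, out / "fhc.csv"))
        files.append(
            _write(_characteristics(included, fhc_df), out / "characteristics.csv", index=False)
        )
        manifest["stages"].append(stage)

        # ---- shape model ------------------------------------------------
        stage = "ssm"
        shapes = [h.contour_array() for h in hips]
        aligned, _mean = sm_mod.procrustes_align(shapes, config.alignment)
        model = sm_mod.fit_ssm(aligned, retention=config.retention)
        model.alignment_config = config.alignment
        sm_mod.save_model(model, out / "model")
        var_df = pd.DataFrame(
            {
                "mode": np.arange(1, len(model.eigenvalues) + 1),
                "eigenvalue": model.eigenvalues,
                "variance_proportion": model.variance_proportions,
                "retained": np.arange(len(model.eigenvalues)) < model.n_retained,
            }
        )
        files.append(_write(var_df, out / "variance_proportions.csv", index=False))
        manifest["n_retained"] = int(model.n_retained)
        manifest["stages"].append(stage)

        # ---- z-scores ---------------------------------------------------
        stage = "zscores"
        zs = sm_mod.zscores_table(model, hips, pre_aligned_shapes=aligned)
        files.append(_write(zs, out / "zscores.csv"))
        manifest["stages"].append(stage)

        # ---- outcomes ---------------------------------------------------
        stage = "outcomes"
        outcomes = hstats.outcomes_table(included, config.ai_threshold)
        files.append(_write(outcomes, out / "outcomes.csv"))
        n_inc = len(included)
        comp = {
            "open_reduction": int(outcomes["o1"].sum()),
            "pelvic_osteotomy": int(sum(r.pelvic_osteotomy for r in included)),
            "residual_only": int(
                sum(
                    (not o.o2_surgery) and o.o4_unfavorable
                    for o in (hstats.derive_outcomes(r, config.ai_threshold) for r in included)
                )
            ),
        }
        unfav = int(outcomes["o4"].sum())
        flow_rows = [(k, v, percent_of(v, n_inc)) for k, v in comp.items()]
        flow_rows.append(("unfavorable", unfav, percent_of(unfav, n_inc)))
        flow_rows.append(("favorable", n_inc - unfav, percent_of(n_inc - unfav, n_inc)))
        outcome_flow = pd.DataFrame(flow_rows, columns=["outcome", "count", "percent"])
        files.append(_write(outcome_flow, out / "outcome_flow.csv", index=False))
        manifest["stages"].append(stage)

        # ---- association suite -----------------------------------------
        stage = "associations"
        assoc = hstats.run_association_suite(zs, fhc_df["morin_category"], outcomes)
        files.append(_write(assoc, out / "associations.csv", index=False))
        qrows = []
        for mode in zs.columns:
            labels, cuts = hstats.quintile_assign(zs[mode].to_numpy())
            sizes = np.bincount(labels, minlength=5)
            qrows.append(
                [mode] + list(sizes) + [f"{c:.3f}" for c in cuts]
            )
        qdf = pd.DataFrame(
            qrows,
            columns=["mode", "n_q0", "n_q1", "n_q2", "n_q3", "n_q4", "cut1", "cut2", "cut3", "cut4"],
        )
        files.append(_write(qdf, out / "quintiles.csv", index=False))
        morin_counts = fhc_df["morin_category"].value_counts().sort_index()
        files.append(
            _write(
                morin_counts.rename_axis("morin_category").rename("n").to_frame(),
                out / "fhc_categories.csv",
            )
        )
        manifest["stages"].append(stage)

        # ---- reliability ------------------------------------------------
        if config.run_reliability and truth is not None:
            stage = "reliability"
            icc_df = reliability_study(
                model,
                hips,
                rater_noise_sd=config.synthetic.rater_noise_sd,
                fraction=config.reliability_fraction,
                seed=int(config.seed) + 1,
            )
            files.append(_write(icc_df, out / "reliability.csv", index=False))
            manifest["stages"].append(stage)

        # ---- mode-shape synthesis --------------------------------------
        stage = "synthesis"
        rows = []
        for m in range(model.n_retained):
            for zval in (-2.5, 0.0, 2.5):
                pts = sm_mod.to_points(sm_mod.synthesize(model, m, zval))
                for i, (x, y) in enumerate(pts):
                    rows.append((m + 1, zval, i, x, y))
        syn_df = pd.DataFrame(rows, columns=["mode", "z_sd", "point_index", "x", "y"])
        files.append(_write(syn_df, out / "synthesized_shapes.csv", index=False))
        manifest["stages"].append(stage)
    except Exception as exc:  # stage failure: record, skip downstream
        log.error("stage %s failed: %s", stage, exc)
        manifest["errors"].append({"stage": stage, "error": str(exc)})

    for f in files:
        manifest["files"][f.name] = _sha256(f)
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return manifest


def reliability_study(
    model,
    hips,
    rater_noise_sd: float,
    fraction: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulated reliability study on a subset of the cohort.

    A seeded ``fraction`` of the hips is re-annotated twice (a second
    session by the same rater and one by a second rater, both with
    ``rater_noise_sd`` pixels of landmark noise). Z-scores of all three
    annotation series, projected onto the primary model, form the
    columns of one two-way table per mode; per-mode ICC(A,1) values are
    combined into the overall coefficient weighted by variance share.
    """
    indices, session2 = reannotate(
        hips, rater_noise_sd, seed=seed, subset_fraction=fraction, rater_id="r1", session=2
    )
    rng_offset = 7919  # distinct stream for the second rater
    _, rater2 = reannotate(
        [hips[int(i)] for i in indices], rater_noise_sd, seed=seed + rng_offset,
        rater_id="r2", session=1,
    )
    primary = [hips[int(i)] for i in indices]
    z_sessions = [
        np.array([sm_mod.zscores(model, h.contour_array()) for h in series])
        for series in (primary, session2, rater2)
    ]
    weights = model.variance_proportions[: model.n_retained]
    result = hstats.reliability_from_sessions(z_sessions, weights)
    rows = [
        (f"mode{m + 1}", result.per_mode_icc[m], result.weights[m])
        for m in range(model.n_retained)
    ]
    df = pd.DataFrame(rows, columns=["mode", "icc", "weight"])
    df.loc[len(df)] = ["overall_weighted", result.overall_icc, 1.0]
    df["n_images"] = len(indices)
    return df
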