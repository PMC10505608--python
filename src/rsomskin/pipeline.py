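"""End-to-end orchestration: per-subject biomarker extraction and cohort analysis.

``run_subject`` executes the full imaging pipeline on one dual-band volume
pair — flattening, stack-wise epidermis segmentation, dermis slab, 3D total
blood volume, and per-band 2D vessel analysis — and returns the six-biomarker
record.  ``run_cohort`` reproduces the study's group analyses over a subject
table: all pairwise comparisons (healthy vs diabetic, the
healthy/NC/LN/HN severity ladder, NnA vs NA), Spearman correlations,
covariate-adjusted logistic regression, and the SVN threshold classifier.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort_stats, layers, preprocess, vessels
from .volio import BandPair, read_band_pair

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "surface_threshold_fraction", "surface_median_window", "flatten_reference_um",
    "jump_limit", "smooth_window", "min_separation_voxels",
    "scales_um", "n_orientations", "cutoff_um", "min_skeleton_px",
    "tbv_threshold_fraction", "tvn_mode", "seed",
}


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters; defaults are the package's decided values."""

    surface_threshold_fraction: float = preprocess.SURFACE_THRESHOLD_FRACTION
    surface_median_window: int = preprocess.SURFACE_MEDIAN_WINDOW
    flatten_reference_um: float | None = None
    jump_limit: int = layers.JUMP_LIMIT
    smooth_window: int = layers.SMOOTH_WINDOW
    min_separation_voxels: int = layers.MIN_SEPARATION
    scales_um: tuple = vessels.SCALES_UM
    n_orientations: int = vessels.N_ORIENTATIONS
    cutoff_um: float = vessels.CUTOFF_UM
    min_skeleton_px: int = vessels.MIN_SKELETON_PX
    tbv_threshold_fraction: float = vessels.TBV_THRESHOLD_FRACTION
    tvn_mode: str = "sum"  # "sum" (svn+lvn) or "full" (full-band junction count)
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scales_um"] = list(d["scales_um"])
        return d


@dataclass
class SubjectResult:
    """Six biomarkers plus intermediate artifacts of one subject run."""

    biomarkers: dict
    boundaries: layers.LayerBoundaries
    slab: layers.DermisSlab
    network_low: vessels.VesselNetwork
    network_high: vessels.VesselNetwork
    shifts: np.ndarray = field(default=None)

    def biomarker_row(self, subject_id: str = "S0000") -> pd.DataFrame:
        row = {"subject_id": subject_id, **self.biomarkers}
        return pd.DataFrame([row])


def run_subject(pair: BandPair, config: PipelineConfig | None = None,
                out_dir: str | Path | None = None,
                subject_id: str = "S0000") -> SubjectResult:
    """Run the imaging pipeline on a co-registered band pair.

    Stages: surface detection on the full-band volume → integer-shift
    flattening of both bands → stack-wise epidermis segmentation on the low
    band → epidermal thickness and signal density → 1.5 mm dermis slab → 3D
    total blood volume on the full band → per-band coronal dermis MIPs →
    matched-filter vessel networks → junction counts.  With ``out_dir``,
    boundary, segment, and biomarker tables are written as CSV.
    """
    cfg = config or PipelineConfig()
    logger.info("subject %s: thresholds surface=%.2f tbv=%.2f cutoff=%.0f µm "
                "prune=%d px", subject_id, cfg.surface_threshold_fraction,
                cfg.tbv_threshold_fraction, cfg.cutoff_um, cfg.min_skeleton_px)

    full = pair.full()
    surface = preprocess.detect_surface(
        full, threshold_fraction=cfg.surface_threshold_fraction,
        median_window=cfg.surface_median_window)
    ref = (None if cfg.flatten_reference_um is None
           else int(round(cfg.flatten_reference_um / full.spacing_um[0])))
    flat_low, shifts = preprocess.flatten(pair.low, surface, reference_index=ref)
    flat_high, _ = preprocess.flatten(pair.high, surface, reference_index=ref)
    flat_full, _ = preprocess.flatten(full, surface, reference_index=ref)

    boundaries = layers.segment_epidermis(
        flat_low, jump_limit=cfg.jump_limit,
        min_separation=cfg.min_separation_voxels, smooth_window=cfg.smooth_window)
    thickness = layers.ep_thickness(boundaries)
    density = layers.ep_signal_density(flat_full, boundaries)
    slab = layers.dermis_mask(boundaries, flat_low)
    tbv = vessels.total_blood_volume(
        flat_full, slab, threshold_fraction=cfg.tbv_threshold_fraction)

    pixel_um = float(np.mean(pair.spacing_um[1:]))
    nets = {}
    for band, grid in (("low", flat_low), ("high", flat_high)):
        mip = vessels.dermis_mip(grid, slab)
        nets[band] = vessels.build_network(
            mip, pixel_um=pixel_um, scales_um=cfg.scales_um,
            n_orientations=cfg.n_orientations,
            min_skeleton_px=cfg.min_skeleton_px, band=band)
    net_full = None
    if cfg.tvn_mode == "full":
        net_full = vessels.build_network(
            vessels.dermis_mip(flat_full, slab), pixel_um=pixel_um,
            scales_um=cfg.scales_um, n_orientations=cfg.n_orientations,
            min_skeleton_px=cfg.min_skeleton_px, band="full")
    svn, lvn, tvn = vessels.combined_counts(
        nets["low"], nets["high"], cutoff_um=cfg.cutoff_um, network_full=net_full)

    result = SubjectResult(
        biomarkers={
            "svn": svn, "lvn": lvn, "tvn": tvn, "tbv_pct": tbv,
            "ep_thickness_um": thickness, "ep_density": density,
        },
        boundaries=boundaries, slab=slab,
        network_low=nets["low"], network_high=nets["high"], shifts=shifts,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        layers.boundaries_to_frame(boundaries).to_csv(
            out_dir / f"{subject_id}_boundaries.csv", index=False)
        seg_rows = [
            {"segment_id": i, "band": band, "length_um": s.length_um,
             "diameter_um": s.diameter_um}
            for band in ("low", "high")
            for i, s in enumerate(nets[band].segments)
        ]
        pd.DataFrame(seg_rows, columns=["segment_id", "band", "length_um",
                                        "diameter_um"]).to_csv(
            out_dir / f"{subject_id}_segments.csv", index=False)
        result.biomarker_row(subject_id).to_csv(
            out_dir / f"{subject_id}_biomarkers.csv", index=False)
        with open(out_dir / f"{subject_id}_manifest.json", "w") as fh:
            json.dump({"subject_id": subject_id, "config": cfg.to_dict()}, fh, indent=1)
    return result


def run_subject_files(low_path, high_path, config: PipelineConfig | None = None,
                      out_dir=None, subject_id: str = "S0000") -> SubjectResult:
    """File-based wrapper around :func:`run_subject`."""
    pair = read_band_pair(low_path, high_path)
    return run_subject(pair, config=config, out_dir=out_dir, subject_id=subject_id)


# ---------------------------------------------------------------------------
# cohort analysis
# ---------------------------------------------------------------------------

#: the study's pairwise contrasts: label, group-a selector, group-b selector
COHORT_CONTRASTS = [
    ("healthy_vs_diabetic", ("healthy",), ("NC", "LN", "HN", "NA", "diabetic")),
    ("healthy_vs_NC", ("healthy",), ("NC",)),
    ("NC_vs_LN", ("NC",), ("LN",)),
    ("LN_vs_HN", ("LN",), ("HN",)),
    ("NnA_vs_NA", ("LN", "HN", "NnA"), ("NA",)),
]

BIOMARKERS = ("svn", "lvn", "tvn", "tbv_pct", "ep_thickness_um", "ep_density")


def run_cohort(table: pd.DataFrame, out_dir: str | Path | None = None,
               covariates=cohort_stats.DEFAULT_COVARIATES,
               min_group_n: int = 3) -> dict:
    """Full cohort analysis of a biomarker table.

    Returns a dict with ``comparisons``, ``correlations``, ``logistic``
    DataFrames, the ``roc`` dict of the SVN threshold classifier, and a
    ``summary`` mean ± SD table; optionally writes the bundle to ``out_dir``.
    Contrast sides with fewer than ``min_group_n`` subjects are skipped with a
    warning.
    """
    import warnings

    if table.empty:
        raise ValueError("empty biomarker table")

    comp_rows = []
    for label, sel_a, sel_b in COHORT_CONTRASTS:
        in_a = table["group"].isin(sel_a)
        in_b = table["group"].isin(sel_b)
        for bm in BIOMARKERS:
            a = table.loc[in_a, bm].dropna().to_numpy()
            b = table.loc[in_b, bm].dropna().to_numpy()
            if len(a) < min_group_n or len(b) < min_group_n:
                warnings.warn(f"skipping {label}/{bm}: group below n={min_group_n}")
                continue
            c = cohort_stats.compare_groups(a, b)
            comp_rows.append({"contrast": label, "biomarker": bm, "test": c.test,
                              "statistic": c.statistic, "p_value": c.p_value,
                              "star": c.star, "n_a": c.n_a, "n_b": c.n_b,
                              "mean_a": c.mean_a, "sd_a": c.sd_a,
                              "mean_b": c.mean_b, "sd_b": c.sd_b})
    comparisons = pd.DataFrame(comp_rows)

    diabetic = table[table["group"] != "healthy"]
    correlations = cohort_stats.spearman_correlations(
        diabetic, x_cols=[c for c in covariates if c in table.columns])

    is_diabetic = (table["group"] != "healthy").astype(int)
    logit_frames = []
    for bm in ("tbv_pct", "svn"):
        try:
            fit = cohort_stats.adjusted_logistic(
                table, is_diabetic, bm, covariates=covariates)
            fit.insert(0, "biomarker", bm)
            logit_frames.append(fit)
        except ValueError as exc:
            warnings.warn(f"logistic fit for {bm} failed: {exc}")
    logistic = pd.concat(logit_frames, ignore_index=True) if logit_frames else pd.DataFrame()

    roc = cohort_stats.threshold_roc(table["svn"].to_numpy(),
                                     is_diabetic.to_numpy())
    summary = cohort_stats.summarize_groups(table, columns=list(BIOMARKERS))

    bundle = {"comparisons": comparisons, "correlations": correlations,
              "logistic": logistic, "roc": roc, "summary": summary}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        comparisons.to_csv(out_dir / "comparisons.csv", index=False)
        correlations.to_csv(out_dir / "correlations.csv", index=False)
        logistic.to_csv(out_dir / "logistic.csv", index=False)
        summary.to_csv(out_dir / "group_summary.csv", index=False)
        with open(out_dir / "roc.json", "w") as fh:
            json.dump(roc, fh, indent=1)
    return bundle
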