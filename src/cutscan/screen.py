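"""Scanning-mutagenesis design and cell-free screen depletion statistics.

The screen expresses nuclease variants in a cell-free system together with
a GFP reporter template (cleavable by the targeting guide) and an RFP
control template. For each variant, replicate and guide target, the
depletion ratio

    r = (GFP_nt / RFP_nt) / (GFP_t / RFP_t)

compares RFP-normalized GFP fluorescence between non-targeting (nt) and
targeting (t) guide reactions; r > 1 means the targeting reaction depleted
the GFP template. Per plate and target, arginine-to-arginine /
glycine-to-glycine wild-type control constructs define a control mean
``mu_p`` and population standard deviation ``sigma_p`` over all control
replicate ratios, and each variant's Z-score is its replicate-mean ratio
standardized by the control standard error:

    Z_v = (mean_t r_vt - mu_p) / (sigma_p / sqrt(n_reps))

QC discards a variant (on a given plate/target) when the coefficient of
variation of its replicate ratios exceeds ``cv_max`` (default 20%) or any
contributing GFP/RFP endpoint is below ``rfu_min`` (default 60 rfu); a
discarded replicate drops the whole variant for that stratum. A variant is
a hit when Z > ``z_threshold`` (default 2) for at least one GFP target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (DegeneratePlateError, MissingControlsError, RangeError,
                     UndefinedRatioError)
from .seqs import AMINO_ACIDS

__all__ = [
    "ProteinSequence", "VariantConstruct", "PlateStats", "DepletionResult",
    "enumerate_scan_variants", "depletion_ratio", "plate_control_stats",
    "variant_zscore", "qc_filter", "call_hits", "analyze_screen",
]


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence with 1-based residue numbering."""

    residues: str

    def __post_init__(self):
        if not self.residues:
            raise ValueError("empty protein sequence")
        bad = set(self.residues.upper()) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"non-canonical residues: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.residues):
            raise RangeError(f"position {position} outside 1..{len(self.residues)}")
        return self.residues[position - 1].upper()


@dataclass(frozen=True)
class VariantConstruct:
    position: int
    original_aa: str
    substituted_aa: str

    def __post_init__(self):
        if self.substituted_aa not in ("R", "G"):
            raise ValueError("scan substitutes only R or G")

    @property
    def is_wt_control(self) -> bool:
        return self.original_aa == self.substituted_aa

    @property
    def variant_id(self) -> str:
        return f"{self.original_aa}{self.position}{self.substituted_aa}"


@dataclass(frozen=True)
class PlateStats:
    plate_id: str
    target_id: str
    mu_p: float
    sigma_p: float
    n_controls: int
    n_reps: int


@dataclass
class DepletionResult:
    variant_id: str
    plate_id: str
    target_id: str
    ratios: list[float]
    mean_ratio: float
    cv: float
    qc_pass: bool
    z_score: float | None = None
    hit: bool = False


def enumerate_scan_variants(protein: ProteinSequence, start: int,
                            end: int) -> list[VariantConstruct]:
    """Enumerate the R/G scanning-mutagenesis design over [start, end].

    Every position yields exactly two constructs (one arginine, one
    glycine substitution); positions whose wild-type residue already is R
    or G yield the corresponding construct flagged as a wild-type control.
    """
    if not (1 <= start <= end <= len(protein)):
        raise RangeError(
            f"range {start}-{end} outside 1..{len(protein)}")
    out = []
    for pos in range(start, end + 1):
        wt = protein.residue(pos)
        for sub in ("R", "G"):
            out.append(VariantConstruct(pos, wt, sub))
    return out


def depletion_ratio(gfp_nt: float, rfp_nt: float, gfp_t: float,
                    rfp_t: float) -> float:
    """Depletion ratio r = (GFP_nt/RFP_nt) / (GFP_t/RFP_t)."""
    for name, v in (("gfp_nt", gfp_nt), ("rfp_nt", rfp_nt),
                    ("gfp_t", gfp_t), ("rfp_t", rfp_t)):
        if not v > 0:
            raise UndefinedRatioError(f"{name}={v!r} is not positive")
    return (gfp_nt / rfp_nt) / (gfp_t / rfp_t)


def plate_control_stats(control_ratios: dict[str, list[float]], *,
                        plate_id: str = "", target_id: str = "") -> PlateStats:
    """Control mean and population SD over all WT-control replicate ratios.

    ``control_ratios`` maps control variant id -> per-replicate depletion
    ratios. The SD divides by |W_p| * |T_p| (population convention).
    """
    if len(control_ratios) < 2:
        raise MissingControlsError(
            f"plate {plate_id!r}/{target_id!r}: need >= 2 WT controls, "
            f"got {len(control_ratios)}")
    flat = np.array([r for rs in control_ratios.values() for r in rs], float)
    n_reps = max(len(rs) for rs in control_ratios.values())
    return PlateStats(plate_id, target_id, float(flat.mean()),
                      float(flat.std(ddof=0)), len(control_ratios), n_reps)


def variant_zscore(mean_ratio: float, stats: PlateStats) -> float:
    """Standard-error-scaled Z-score of a variant's mean depletion ratio."""
    if stats.sigma_p == 0:
        raise DegeneratePlateError(
            f"plate {stats.plate_id!r}: control SD is zero")
    return (mean_ratio - stats.mu_p) / (stats.sigma_p / math.sqrt(stats.n_reps))


def qc_filter(ratios: list[float], endpoints: list[float], *,
              cv_max: float = 20.0, rfu_min: float = 60.0) -> tuple[bool, float]:
    """QC a variant's replicate set; returns (pass, cv_percent).

    Only variants with CV strictly below ``cv_max`` are kept (CV =
    100 * population SD / mean of the replicate ratios); any
    contributing fluorescence endpoint below ``rfu_min`` also fails the
    variant.
    """
    arr = np.asarray(ratios, float)
    cv = float(100.0 * arr.std(ddof=0) / arr.mean()) if arr.mean() != 0 else math.inf
    ok = cv < cv_max and all(e >= rfu_min for e in endpoints)
    return ok, cv


def call_hits(results: list[DepletionResult], *,
              z_threshold: float = 2.0) -> set[str]:
    """Hit set: variants with Z > threshold for >= 1 target (QC-passing)."""
    hits = set()
    for res in results:
        if res.qc_pass and res.z_score is not None and res.z_score > z_threshold:
            hits.add(res.variant_id)
            res.hit = True
    for res in results:
        if res.variant_id in hits and res.qc_pass:
            res.hit = True
    return hits


REQUIRED_COLUMNS = ["plate_id", "variant_id", "replicate", "guide_kind",
                    "target_id", "gfp_rfu", "rfp_rfu"]


def analyze_screen(records: pd.DataFrame, wt_controls: set[str], *,
                   cv_max: float = 20.0, rfu_min: float = 60.0,
                   z_threshold: float = 2.0) -> pd.DataFrame:
    """Full screen analysis from a long-format plate table.

    ``records`` needs columns plate_id, variant_id, replicate, guide_kind
    (``target``/``non_target``), target_id, gfp_rfu, rfp_rfu; each
    (variant, replicate, target) must carry both guide kinds.
    ``wt_controls`` names the wild-type control variant ids. Statistics
    are computed per (plate_id, target_id) stratum. Returns one row per
    variant x target with ratios, CV, QC flag, Z and hit call.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")

    # one row per (plate, target, variant, replicate) with both arms
    wide = records.pivot_table(
        index=["plate_id", "target_id", "variant_id", "replicate"],
        columns="guide_kind", values=["gfp_rfu", "rfp_rfu"],
        aggfunc="first").reset_index()
    wide.columns = ["_".join(c).rstrip("_") if c[1] else c[0]
                    for c in wide.columns]
    for col in ("gfp_rfu_target", "gfp_rfu_non_target",
                "rfp_rfu_target", "rfp_rfu_non_target"):
        if col not in wide:
            raise ValueError(f"records lack {col.rsplit('_', 1)[-1]} arm")
    arms = wide[["gfp_rfu_non_target", "rfp_rfu_non_target",
                 "gfp_rfu_target", "rfp_rfu_target"]].to_numpy(float)
    valid = (arms > 0).all(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        wide["ratio"] = np.where(
            valid,
            (arms[:, 0] / arms[:, 1]) / (arms[:, 2] / arms[:, 3]),
            np.nan)
    wide["min_endpoint"] = arms.min(axis=1)

    rows: list[DepletionResult] = []
    for (plate, target), grp in wide.groupby(["plate_id", "target_id"],
                                             sort=True):
        agg = grp.groupby("variant_id", sort=True).agg(
            mean_ratio=("ratio", "mean"),
            sd=("ratio", lambda r: r.std(ddof=0)),
            n=("ratio", "count"),
            n_reps=("ratio", "size"),
            min_endpoint=("min_endpoint", "min"))
        controls = {v: list(g.ratio.dropna())
                    for v, g in grp[grp.variant_id.isin(wt_controls)]
                    .groupby("variant_id", sort=True)}
        stats = plate_control_stats(controls, plate_id=str(plate),
                                    target_id=str(target))
        for variant, row in agg.iterrows():
            ratios = list(grp.ratio[grp.variant_id == variant].dropna())
            cv = (100.0 * row.sd / row.mean_ratio
                  if row.n and row.mean_ratio else math.inf)
            # a variant with any excluded replicate is dropped entirely
            qc_ok = bool(cv < cv_max and row.min_endpoint >= rfu_min
                         and row.n == row.n_reps and row.n > 0)
            z = variant_zscore(float(row.mean_ratio), stats) \
                if qc_ok else None
            rows.append(DepletionResult(str(variant), str(plate),
                                        str(target), ratios,
                                        float(row.mean_ratio), float(cv),
                                        qc_ok, z))

    call_hits(rows, z_threshold=z_threshold)
    return pd.DataFrame(
        {"variant_id": r.variant_id, "plate_id": r.plate_id,
         "target_id": r.target_id, "mean_ratio": r.mean_ratio,
         "cv": r.cv, "qc_pass": r.qc_pass, "z_score": r.z_score,
         "hit": r.hit, "is_wt_control": r.variant_id in wt_controls}
        for r in rows)
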