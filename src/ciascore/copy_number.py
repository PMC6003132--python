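"""GC and reference normalization of bin counts to relative copy number.

Raw per-bin counts carry two dominant biases: a smooth dependence on window
GC content introduced by amplification/library prep, and locus-specific
mappability/amplification effects that are stable across samples.  The first
is removed by dividing by a smooth fit of count versus GC; the second by
dividing by a panel-of-normals reference profile.  The result is the
relative copy number xi, scaled so the diploid expectation is 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genome_bins import BinMap, RawCountProfile

MIN_GC_BINS = 50
LOESS_SPAN = 0.3
#: below this many usable bins the LOESS fit is replaced by decile medians
LOESS_MIN_BINS = 500


class NormalizationError(ValueError):
    pass


@dataclass
class ReferenceProfile:
    """Per-bin expected normalized depth from a panel of diploid samples.

    ``values`` has median 1 over usable bins; NaN where unusable.
    """

    values: np.ndarray
    usable: np.ndarray
    n_panel: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.usable = np.asarray(self.usable, dtype=bool)
        if len(self.values) != len(self.usable):
            raise ValueError("values and usable mask differ in length")
        ok = self.values[self.usable]
        if not (np.isfinite(ok).all() and (ok > 0).all()):
            raise ValueError("reference must be finite and positive on usable bins")

    def to_tsv(self, path: str | Path, bin_map: BinMap) -> None:
        df = bin_map.bins[["chrom", "start", "end"]].copy()
        df["value"] = self.values
        df["usable"] = self.usable.astype(int)
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path: str | Path, n_panel: int = 1) -> "ReferenceProfile":
        df = pd.read_csv(path, sep="\t")
        return cls(df["value"].to_numpy(), df["usable"].to_numpy(dtype=bool), n_panel)


@dataclass
class CopyNumberProfile:
    """Per-bin relative copy number xi (diploid expectation 2)."""

    sample_id: str
    xi: np.ndarray
    usable: np.ndarray

    def __post_init__(self) -> None:
        self.xi = np.asarray(self.xi, dtype=float)
        self.usable = np.asarray(self.usable, dtype=bool)
        ok = self.xi[self.usable]
        if len(ok) and not (np.isfinite(ok).all() and (ok > 0).all()):
            raise ValueError("xi must be finite and positive on usable bins")

    def to_tsv(self, path: str | Path, bin_map: BinMap) -> None:
        df = bin_map.bins[["chrom", "start", "end"]].copy()
        df["value"] = self.xi
        df["usable"] = self.usable.astype(int)
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _gc_fit(counts: np.ndarray, gc: np.ndarray, fit_mask: np.ndarray,
            span: float) -> np.ndarray:
    """Expected count as a smooth function of GC, evaluated at every bin."""
    x, y = gc[fit_mask], counts[fit_mask].astype(float)
    if fit_mask.sum() >= LOESS_MIN_BINS:
        fitted = lowess(y, x, frac=span, it=2, xvals=gc)
    else:
        # decile-median fallback: robust at small bin counts
        edges = np.nanquantile(x, np.linspace(0, 1, 11))
        edges[0], edges[-1] = -np.inf, np.inf
        which = np.searchsorted(edges, gc, side="right") - 1
        which = np.clip(which, 0, 9)
        med = np.full(10, np.nan)
        which_fit = which[fit_mask]
        for d in range(10):
            sel = y[which_fit == d]
            if len(sel):
                med[d] = np.median(sel)
        overall = np.median(y)
        med = np.where(np.isfinite(med), med, overall)
        fitted = med[which]
    floor = 0.01 * max(np.nanmedian(fitted), 1e-12)
    return np.where(np.isfinite(fitted) & (fitted > floor), fitted, floor)


def gc_normalize(profile: RawCountProfile, bin_map: BinMap,
                 span: float = LOESS_SPAN) -> np.ndarray:
    """Correct per-bin counts for GC bias.

    Fits expected count as a smooth (LOESS) function of GC fraction over
    usable bins and returns ``count / fit * median(count)``, so the output
    stays on the raw-count scale.  NaN on unusable bins.
    """
    counts = np.asarray(profile.bin_counts, dtype=float)
    if len(counts) != bin_map.n_bins:
        raise NormalizationError("profile length does not match bin map")
    gc = bin_map.gc_fraction
    if not np.isfinite(gc).any():
        raise NormalizationError(
            "bin map has no GC fractions; rebuild it from a FASTA to enable "
            "GC normalization"
        )
    usable = bin_map.usable & np.isfinite(gc)
    if usable.sum() < MIN_GC_BINS:
        raise NormalizationError(
            f"need >= {MIN_GC_BINS} usable bins with GC, got {int(usable.sum())}"
        )
    if counts[usable].sum() == 0:
        raise NormalizationError("all bin counts are zero")

    fit = _gc_fit(counts, gc, usable, span)
    corrected = counts / fit * np.median(counts[usable])
    corrected[~usable] = np.nan
    return corrected


def build_reference(panel: list[np.ndarray], min_reference: float = 0.1,
                    max_cv: float = 0.5) -> ReferenceProfile:
    """Median-of-panel reference from GC-corrected depth profiles.

    Each profile is scaled to its own median before taking the per-bin
    median.  Bins with reference < ``min_reference`` or coefficient of
    variation > ``max_cv`` across the panel are masked unusable.
    """
    if not panel:
        raise ValueError("panel is empty")
    lengths = {len(p) for p in panel}
    if len(lengths) != 1:
        raise ValueError("panel profiles are not aligned to the same bin map")
    mat = np.vstack([np.asarray(p, dtype=float) for p in panel])
    medians = np.nanmedian(np.where(mat > 0, mat, np.nan), axis=1)
    if not np.isfinite(medians).all() or (medians <= 0).any():
        raise ValueError("a panel sample has no positive depth")
    scaled = mat / medians[:, None]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        ref = np.nanmedian(scaled, axis=0)
        mean = np.nanmean(scaled, axis=0)
        sd = np.nanstd(scaled, axis=0, ddof=1) if len(panel) > 1 else np.zeros_like(ref)
    cv = np.divide(sd, mean, out=np.full_like(ref, np.inf), where=mean > 0)
    usable = np.isfinite(ref) & (ref >= min_reference) & (cv <= max_cv)
    ref = np.where(usable, ref, np.nan)
    return ReferenceProfile(ref, usable, n_panel=len(panel))


def pseudo_reference(bin_map: BinMap) -> ReferenceProfile:
    """All-ones reference for running without a panel of normals.

    Locus-specific bias then passes through uncorrected; a real panel is
    preferred whenever available.
    """
    warnings.warn(
        "using a flat pseudo-reference; locus-specific bias is not corrected",
        stacklevel=2,
    )
    usable = bin_map.usable.copy()
    values = np.where(usable, 1.0, np.nan)
    return ReferenceProfile(values, usable, n_panel=0)


def to_copy_number(
    depth: np.ndarray,
    reference: ReferenceProfile,
    bin_map: BinMap,
    sample_id: str = "sample",
    include_sex_chroms: bool = False,
) -> CopyNumberProfile:
    """Convert GC-corrected depth to relative copy number xi.

    xi = 2 * (depth / sample-median depth) / reference, recentred so the
    median over autosomal usable bins is exactly 2.  Sex-chromosome bins are
    masked unless ``include_sex_chroms`` (mixed-sex cohorts would otherwise
    read X dosage as imbalance).
    """
    depth = np.asarray(depth, dtype=float)
    usable = reference.usable & np.isfinite(depth) & bin_map.usable
    if usable.sum() < MIN_GC_BINS:
        raise NormalizationError(
            f"reference usable on only {int(usable.sum())} bins"
        )
    med = np.median(depth[usable])
    if not med > 0:
        raise NormalizationError("sample median depth is zero")
    with np.errstate(invalid="ignore", divide="ignore"):
        xi = 2.0 * (depth / med) / reference.values
    if not include_sex_chroms:
        usable &= bin_map.is_autosome
    usable &= np.isfinite(xi) & (xi > 0)

    autosomal = usable & bin_map.is_autosome
    centre_mask = autosomal if autosomal.any() else usable
    centre = np.median(xi[centre_mask])
    if centre > 0:
        xi = xi * (2.0 / centre)
    xi = np.where(usable, xi, np.nan)
    return CopyNumberProfile(sample_id, xi, usable)


def plot_profile(cn: CopyNumberProfile, bin_map: BinMap, path: str | Path,
                 ylim: tuple[float, float] = (0, 6)) -> None:
    """Genome-wide xi scatter with chromosome boundaries, saved as PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(12, 3))
    x = np.arange(bin_map.n_bins)
    ax.scatter(x[cn.usable], cn.xi[cn.usable], s=4, c="tab:blue")
    ax.axhline(2.0, color="grey", lw=0.8, ls="--")
    boundaries = bin_map.bins.groupby("chrom", sort=False).head(1).index
    for b in boundaries[1:]:
        ax.axvline(b - 0.5, color="lightgrey", lw=0.6)
    mids = bin_map.bins.groupby("chrom", sort=False).apply(
        lambda g: g.index[len(g) // 2], include_groups=False
    )
    ax.set_xticks(mids, mids.index, rotation=90, fontsize=6)
    ax.set_ylim(*ylim)
    ax.set_ylabel("relative copy number")
    ax.set_title(cn.sample_id)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
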