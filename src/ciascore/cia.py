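"""The chromosomal imbalance analysis (CIA) score.

Each usable bin's deviation from diploid is summarized as
``Z_i = sqrt(|log2(xi / 2)|)`` — zero exactly at xi = 2, symmetric in gains
and losses on the log scale, with the square root damping extreme bins.
The CIA score sums Z over the bins ranked (ascending) between the m-th and
p-th percentile (defaults m = 95, p = 99): the window captures the
high-imbalance tail of the genome while excluding the top 1% of bins, which
are the most exposed to artefacts.  A sample is called positive when its
score exceeds the cutoff (default 24).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .copy_number import CopyNumberProfile

DEFAULT_M = 95.0
DEFAULT_P = 99.0
DEFAULT_CUTOFF = 24.0
MIN_USABLE_BINS = 100


@dataclass
class ZProfile:
    """Per-bin non-negative deviation values; NaN on unusable bins."""

    sample_id: str
    z: np.ndarray
    usable: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.usable = np.asarray(self.usable, dtype=bool)
        ok = self.z[self.usable]
        if len(ok) and not (np.isfinite(ok).all() and (ok >= 0).all()):
            raise ValueError("Z must be finite and non-negative on usable bins")


@dataclass
class CIAResult:
    sample_id: str
    cia_score: float
    m: float
    p: float
    n_usable_bins: int
    window_bins: np.ndarray  # genomic (global bin-map) indices summed
    cutoff: float | None = None
    call: str | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = dict(
            sample_id=self.sample_id,
            cia_score=round(float(self.cia_score), 6),
            m=self.m,
            p=self.p,
            n_usable_bins=self.n_usable_bins,
            n_window_bins=int(len(self.window_bins)),
            cutoff=self.cutoff,
            call=self.call,
        )
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def z_transform(cn: CopyNumberProfile) -> ZProfile:
    """Z_i = sqrt(|log2(xi / 2)|) on usable bins."""
    xi = cn.xi
    bad = cn.usable & ~(xi > 0)
    if bad.any():
        raise ValueError(
            f"xi must be positive on usable bins; offending bin index "
            f"{int(np.flatnonzero(bad)[0])}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.sqrt(np.abs(np.log2(xi / 2.0)))
    z = np.where(cn.usable, z, np.nan)
    return ZProfile(cn.sample_id, z, cn.usable.copy())


def percentile_window(n: int, m: float, p: float) -> tuple[int, int]:
    """1-based inclusive rank bounds (ceil(m/100*n), floor(p/100*n))."""
    return math.ceil(m / 100.0 * n), math.floor(p / 100.0 * n)


def cia_score(z: ZProfile, m: float = DEFAULT_M, p: float = DEFAULT_P) -> CIAResult:
    """Sum Z over the bins ranked between the m-th and p-th percentile.

    Usable bins are sorted ascending by Z (ties broken by genomic order);
    the window is 1-based ranks ceil(m/100*N) .. floor(p/100*N) inclusive.
    """
    if not (0 <= m < p <= 100):
        raise ValueError(f"need 0 <= m < p <= 100, got m={m}, p={p}")
    idx = np.flatnonzero(z.usable)
    n = len(idx)
    if n < MIN_USABLE_BINS:
        raise ValueError(
            f"need >= {MIN_USABLE_BINS} usable bins for a stable percentile "
            f"window, got {n}"
        )
    order = idx[np.argsort(z.z[idx], kind="stable")]
    lo, hi = percentile_window(n, m, p)
    window = order[lo - 1 : hi] if hi >= lo else order[:0]
    score = float(z.z[window].sum())
    return CIAResult(z.sample_id, score, m, p, n, np.sort(window))


def classify(result: CIAResult, cutoff: float = DEFAULT_CUTOFF) -> CIAResult:
    """Set the binary call: positive iff score is strictly above the cutoff."""
    if not math.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    result.cutoff = float(cutoff)
    result.call = "positive" if result.cia_score > cutoff else "negative"
    return result


def score_sample(cn: CopyNumberProfile, m: float = DEFAULT_M,
                 p: float = DEFAULT_P,
                 cutoff: float = DEFAULT_CUTOFF) -> CIAResult:
    """Convenience: z-transform, score and classify one sample."""
    return classify(cia_score(z_transform(cn), m=m, p=p), cutoff=cutoff)
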