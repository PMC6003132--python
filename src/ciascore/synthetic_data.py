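"""Synthetic shallow-WGS bin-count data with the structure the method assumes.

Profiles are generated as overdispersed counts whose per-bin expectation is
proportional to bin width x mixture copy number x a smooth GC response,
scaled to a target read total (default 5 million reads per sample, the
depth regime the scoring method is designed for).  A tumour sample is a
mixture: a fraction ``tumour_fraction`` of the DNA carries the configured
copy-number events, the remainder is diploid, so an event with copy number
c contributes expected relative copy number t*c + (1 - t)*2.

The generator emulates bias and noise (GC response, locus-stable panel
structure via shared GC, negative-binomial overdispersion) but not
amplification chemistry, mappability holes or base-level errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import pysam

from . import cia, copy_number
from .genome_bins import BinMap, RawCountProfile, build_bin_map

DEFAULT_TOTAL_READS = 5_000_000
#: variance / mean of the count noise (1.0 = Poisson); shallow-WGS libraries
#: are mildly overdispersed
DEFAULT_DISPERSION = 1.3


@dataclass(frozen=True)
class CNVEvent:
    """A copy-number event spanning whole bins of one chromosome.

    ``start_bin``/``end_bin`` are within-chromosome bin indices, half-open.
    ``copy_number`` is the tumour-cell copy number (diploid = 2).
    """

    chrom: str
    start_bin: int
    end_bin: int
    copy_number: float

    def __post_init__(self) -> None:
        if self.copy_number <= 0:
            raise ValueError("event copy number must be positive")
        if not 0 <= self.start_bin < self.end_bin:
            raise ValueError("need 0 <= start_bin < end_bin")


@dataclass(frozen=True)
class GCBias:
    """Smooth unimodal GC response: f(gc) = max(floor, 1 - curvature*(gc-peak)^2)."""

    peak: float = 0.45
    curvature: float = 6.0
    floor: float = 0.05

    def __call__(self, gc: np.ndarray) -> np.ndarray:
        resp = 1.0 - self.curvature * (np.asarray(gc, dtype=float) - self.peak) ** 2
        return np.clip(resp, self.floor, None)


@dataclass(frozen=True)
class SimulationConfig:
    events: tuple[CNVEvent, ...] = ()
    tumour_fraction: float = 0.0
    total_reads: int = DEFAULT_TOTAL_READS
    gc_bias: GCBias = field(default_factory=GCBias)
    dispersion: float = DEFAULT_DISPERSION
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumour_fraction <= 1.0:
            raise ValueError("tumour_fraction must be in [0, 1]")
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")
        if self.dispersion < 1.0:
            raise ValueError("dispersion is variance/mean and must be >= 1")


def toy_bin_map(n_chroms: int = 10, chrom_length: int = 30_000_000,
                bin_size: int = 1_000_000, gc_range: tuple[float, float] = (0.35, 0.55),
                seed: int = 0) -> BinMap:
    """Small autosome-only genome (default 10 x 30 Mb = 300 bins) with
    reproducible synthetic GC fractions."""
    sizes = {f"chr{i + 1}": chrom_length for i in range(n_chroms)}
    bm = build_bin_map(chrom_sizes=sizes, bin_size=bin_size, genome_build="toy")
    return with_synthetic_gc(bm, gc_range=gc_range, seed=seed)


def with_synthetic_gc(bin_map: BinMap, gc_range: tuple[float, float] = (0.35, 0.55),
                      seed: int = 0) -> BinMap:
    """Attach reproducible synthetic GC fractions to a GC-less bin map."""
    rng = np.random.default_rng(seed)
    bins = bin_map.bins.copy()
    bins["gc_fraction"] = rng.uniform(*gc_range, size=len(bins))
    return BinMap(bin_map.genome_build, bins, bin_size=bin_map.bin_size)


def expected_mixture_cn(config: SimulationConfig, bin_map: BinMap) -> np.ndarray:
    """Per-bin expected relative copy number t*c + (1 - t)*2."""
    cn = np.full(bin_map.n_bins, 2.0)
    t = config.tumour_fraction
    offsets = bin_map._chrom_offsets()
    for ev in config.events:
        if ev.chrom not in offsets:
            raise ValueError(f"event chromosome {ev.chrom} not in bin map")
        start, n = offsets[ev.chrom]
        if ev.end_bin > n:
            raise ValueError(f"event extends past {ev.chrom} ({ev.end_bin} > {n})")
        cn[start + ev.start_bin : start + ev.end_bin] = t * ev.copy_number + (1 - t) * 2.0
    return cn


def simulate_profile(config: SimulationConfig, bin_map: BinMap,
                     sample_id: str = "sim") -> RawCountProfile:
    """Draw one bin-count profile; identical config + seed is bit-reproducible."""
    bins = bin_map.bins
    widths = (bins["end"] - bins["start"]).to_numpy(dtype=float)
    gc = bin_map.gc_fraction
    gc_resp = np.where(np.isfinite(gc), config.gc_bias(gc), 1.0)
    cn = expected_mixture_cn(config, bin_map)
    weight = widths * (cn / 2.0) * gc_resp
    weight[~bin_map.usable] = 0.0
    if weight.sum() <= 0:
        raise ValueError("no usable bins to simulate")
    lam = weight / weight.sum() * config.total_reads

    rng = np.random.default_rng(config.seed)
    if config.dispersion <= 1.0 + 1e-12:
        counts = rng.poisson(lam)
    else:
        # gamma-Poisson mixture: variance = dispersion * mean
        excess = config.dispersion - 1.0
        shape = lam / excess
        mean = np.zeros_like(lam)
        pos = shape > 0
        mean[pos] = rng.gamma(shape[pos], excess)
        counts = rng.poisson(mean)
    return RawCountProfile(sample_id, counts)


def default_case_model(altered_fraction: float = 0.12,
                       tf_range: tuple[float, float] = (0.4, 0.9),
                       copy_numbers: Sequence[float] = (3.0, 3.0, 1.0),
                       ) -> Callable[[np.random.Generator, BinMap],
                                     tuple[tuple[CNVEvent, ...], float]]:
    """Case generator: contiguous per-chromosome events (mostly single-copy
    gains, some losses) covering ``altered_fraction`` of the genome, with
    tumour fraction drawn uniformly from ``tf_range``."""

    def draw(rng: np.random.Generator, bin_map: BinMap):
        chrom_bins = bin_map.bins.groupby("chrom", sort=False).size()
        autosomes = [c for c in chrom_bins.index if c not in
                     {"chrX", "chrY", "X", "Y"}]
        target = int(round(altered_fraction * int(chrom_bins[autosomes].sum())))
        events: list[CNVEvent] = []
        altered = 0
        for chrom in rng.permutation(autosomes):
            if altered >= target:
                break
            n = int(chrom_bins[chrom])
            span = min(n, max(1, target - altered))
            start = int(rng.integers(0, n - span + 1))
            cn = float(rng.choice(copy_numbers))
            events.append(CNVEvent(chrom, start, start + span, cn))
            altered += span
        tf = float(rng.uniform(*tf_range))
        return tuple(events), tf

    return draw


def simulate_cohort(
    n_cases: int,
    n_controls: int,
    bin_map: BinMap | None = None,
    case_event_model: Callable | None = None,
    n_panel: int = 20,
    total_reads: int = DEFAULT_TOTAL_READS,
    dispersion: float = DEFAULT_DISPERSION,
    m: float = cia.DEFAULT_M,
    p: float = cia.DEFAULT_P,
    cutoff: float = cia.DEFAULT_CUTOFF,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a labelled cohort and run it through the full pipeline.

    A diploid panel of ``n_panel`` samples (GC-normalized) provides the
    reference; every sample is then counted, normalized and scored.  Returns
    (scores, truth): scores has columns sample_id/score/label/call, truth
    records each sample's tumour fraction and altered-bin count.
    """
    if n_cases < 1 or n_controls < 1:
        raise ValueError("need at least one case and one control")
    if bin_map is None:
        bin_map = toy_bin_map()
    if case_event_model is None:
        case_event_model = default_case_model()
    rng = np.random.default_rng(seed)

    def child_seed() -> int:
        return int(rng.integers(0, 2**31 - 1))

    base = SimulationConfig(total_reads=total_reads, dispersion=dispersion)
    panel_depths = []
    for i in range(n_panel):
        prof = simulate_profile(replace(base, seed=child_seed()), bin_map,
                                sample_id=f"panel_{i}")
        panel_depths.append(copy_number.gc_normalize(prof, bin_map))
    reference = copy_number.build_reference(panel_depths)

    rows, truth_rows = [], []
    specs = [("case", i) for i in range(n_cases)] + [
        ("control", i) for i in range(n_controls)]
    for label, i in specs:
        if label == "case":
            events, tf = case_event_model(rng, bin_map)
        else:
            events, tf = (), 0.0
        config = replace(base, events=events, tumour_fraction=tf,
                         seed=child_seed())
        sid = f"{label}_{i}"
        prof = simulate_profile(config, bin_map, sample_id=sid)
        depth = copy_number.gc_normalize(prof, bin_map)
        cn = copy_number.to_copy_number(depth, reference, bin_map, sample_id=sid)
        result = cia.score_sample(cn, m=m, p=p, cutoff=cutoff)
        rows.append(dict(sample_id=sid, score=result.cia_score, label=label,
                         call=result.call))
        truth_rows.append(dict(
            sample_id=sid, label=label, tumour_fraction=tf,
            n_altered_bins=sum(ev.end_bin - ev.start_bin for ev in events),
            events=";".join(
                f"{ev.chrom}:{ev.start_bin}-{ev.end_bin}x{ev.copy_number:g}"
                for ev in events),
        ))
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def simulate_alignments(profile: RawCountProfile, bin_map: BinMap,
                        path: str | Path, read_length: int = 100,
                        seed: int = 0) -> None:
    """Write a coordinate-sorted SAM/BAM realizing the profile's counts.

    Each bin emits exactly its count of single-end reads at uniform start
    positions inside the bin (mapq 60, proper flags), so ``count_reads`` on
    the output reproduces the profile exactly.
    """
    if read_length > bin_map.bin_size:
        raise ValueError("read_length exceeds the bin size")
    if len(profile.bin_counts) != bin_map.n_bins:
        raise ValueError("profile length does not match bin map")
    rng = np.random.default_rng(seed)
    path = Path(path)
    mode = "wb" if path.suffix == ".bam" else "w"
    lengths = bin_map.chrom_lengths
    header = dict(
        HD=dict(VN="1.6", SO="coordinate"),
        SQ=[dict(SN=c, LN=int(lengths[c])) for c in bin_map.chromosomes],
    )
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        serial = 0
        for chrom in bin_map.chromosomes:
            grp = bin_map.bins[bin_map.bins["chrom"] == chrom]
            chrom_positions = []
            for row, count in zip(grp.itertuples(), profile.bin_counts[grp.index]):
                if count == 0:
                    continue
                hi = max(row.start + 1, row.end - read_length + 1)
                chrom_positions.extend(
                    int(p) for p in rng.integers(row.start, hi, size=int(count))
                )
            tid = out.get_tid(chrom)
            for pos in sorted(chrom_positions):
                a = pysam.AlignedSegment(out.header)
                a.query_name = f"read_{serial}"
                a.reference_id = tid
                a.reference_start = pos
                a.mapping_quality = 60
                a.cigarstring = f"{read_length}M"
                a.query_sequence = "A" * read_length
                a.query_qualities = pysam.qualitystring_to_array("I" * read_length)
                a.flag = 0
                out.write(a)
                serial += 1
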