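"""Per-nucleotide antisense profiles and their summaries.

A profile records, for every spliced position of one transcript, the
(normalized) number of filtered 22G reads attributed to that position.  The
default counting rule attributes each read once, at its 5' end on the
antisense strand — the figures being emulated are read-count histograms,
not coverage — with full coverage retained for visualization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .reads import ANTISENSE, SENSE, AlignmentHit, NormalizationFactors
from .reference import TranscriptModel

FIVE_PRIME_END = "five_prime_end"
FULL_COVERAGE = "full_coverage"


@dataclass
class PositionalProfile:
    transcript_id: str
    values: np.ndarray
    normalization: str = "raw"
    counting_rule: str = FIVE_PRIME_END

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if (self.values < 0).any():
            raise ValueError("profile values must be non-negative")

    @property
    def length(self) -> int:
        return self.values.size

    @property
    def total(self) -> float:
        return float(self.values.sum())


@dataclass
class BinVector:
    """Length-normalized 10-bin summary of a profile, ordered 5'->3'."""

    transcript_id: str
    bins: np.ndarray
    total: float

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=np.float64)


@dataclass(frozen=True)
class RegionSummary:
    """Antisense signal split into proximal (near the piRNA site) and distal."""

    proximal: float
    distal: float
    window_nt: int

    @property
    def total(self) -> float:
        return self.proximal + self.distal

    @property
    def distal_proximal_ratio(self) -> float:
        return self.distal / self.proximal if self.proximal > 0 else float("inf")


def positional_profile(hits: Iterable[AlignmentHit], t: TranscriptModel,
                       norm: NormalizationFactors | None = None,
                       counting_rule: str = FIVE_PRIME_END) -> PositionalProfile:
    """Accumulate filtered hits into a per-position profile of transcript ``t``.

    Hits are expected to be pre-filtered (antisense, 22G class, unique);
    hits on other transcripts are ignored so per-transcript profiling over
    a shared hit list is convenient.
    """
    if counting_rule not in (FIVE_PRIME_END, FULL_COVERAGE):
        raise ValueError(f"unknown counting rule {counting_rule!r}")
    values = np.zeros(t.spliced_length, dtype=np.float64)
    for h in hits:
        if h.transcript_id != t.id:
            continue
        if h.start < 0 or h.end > t.spliced_length:
            raise ValueError(
                f"hit [{h.start},{h.end}) outside transcript {t.id}")
        if counting_rule == FIVE_PRIME_END:
            values[h.five_prime_position] += 1.0
        else:
            values[h.start:h.end] += 1.0
    mode = "raw"
    if norm is not None and norm.mode != "raw":
        values /= norm.denominator
        mode = norm.mode
    return PositionalProfile(t.id, values, normalization=mode,
                             counting_rule=counting_rule)


def proximal_distal(profile: PositionalProfile, site: tuple[int, int],
                    window: int = 200) -> RegionSummary:
    """Partition profile mass around a piRNA target site.

    Proximal is everything within ``window`` nt of the site (site interval
    extended by the window on both sides, clipped to the transcript);
    distal is the remainder, so proximal + distal equals the profile total.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    s, e = site
    if not (0 <= s < e <= profile.length):
        raise ValueError(f"site {site} outside transcript {profile.transcript_id}")
    lo = max(0, s - window)
    hi = min(profile.length, e + window)
    proximal = float(profile.values[lo:hi].sum())
    distal = float(profile.values[:lo].sum() + profile.values[hi:].sum())
    return RegionSummary(proximal=proximal, distal=distal, window_nt=window)


def bin_edges(length: int, n_bins: int = 10) -> np.ndarray:
    """Bin b covers positions [floor(b*L/n), floor((b+1)*L/n))."""
    return np.array([(b * length) // n_bins for b in range(n_bins + 1)], dtype=int)


def bin_profile(profile: PositionalProfile, n_bins: int = 10) -> BinVector:
    """Sum the profile into ``n_bins`` evenly spaced bins along the transcript.

    Every position belongs to exactly one bin, so the bin sums conserve the
    profile total exactly.
    """
    L = profile.length
    if L < n_bins:
        raise ValueError(f"transcript length {L} shorter than {n_bins} bins")
    edges = bin_edges(L, n_bins)
    sums = np.add.reduceat(profile.values, edges[:-1])
    return BinVector(profile.transcript_id, sums, total=profile.total)


def exon_intron_counts(genomic_hits: Iterable[AlignmentHit], t: TranscriptModel,
                       library_total: int | None = None):
    """Assign genomic-coordinate hits to the exon or intron holding their 5' end.

    Returns a DataFrame with one row per feature in transcript order
    (exon_1, intron_1, exon_2, ...), raw counts, and reads-per-million when
    a library size is given.  Single-exon transcripts have no intron rows.
    """
    import pandas as pd

    features: list[tuple[str, int, int]] = []
    for i, (s, e) in enumerate(t.exons, start=1):
        features.append((f"exon_{i}", s, e))
    for i, (s, e) in enumerate(t.introns, start=1):
        features.append((f"intron_{i}", s, e))
    features.sort(key=lambda f: f[1])

    span_start, span_end = t.genomic_span
    counts = {name: 0 for name, _, _ in features}
    for h in genomic_hits:
        if h.transcript_id != t.id:
            continue
        if h.start < span_start or h.end > span_end:
            raise ValueError(
                f"hit [{h.start},{h.end}) outside genomic span of {t.id}")
        # 5' end in genomic coordinates depends on transcript strand
        if t.strand == "+":
            p5 = h.end - 1 if h.orientation == ANTISENSE else h.start
        else:
            p5 = h.start if h.orientation == ANTISENSE else h.end - 1
        for name, s, e in features:
            if s <= p5 < e:
                counts[name] += 1
                break
    rows = []
    for name, s, e in features:
        row = {"feature": name, "start": s, "end": e, "count": counts[name]}
        if library_total:
            row["rpm"] = counts[name] * 1e6 / library_total
        rows.append(row)
    return pd.DataFrame(rows)


def ip_enrichment(profile_ip: PositionalProfile, profile_ctrl: PositionalProfile,
                  pseudocount: float = 1.0,
                  regions: Mapping[str, tuple[int, int]] | None = None,
                  n_bins: int | None = None) -> dict[str, float]:
    """Fold enrichment of an IP profile over its control, per region or bin.

    Both profiles must share transcript and normalization (reads-per-million
    is the intended mode, so the pseudocount default of 1 means one read per
    million).  With neither ``regions`` nor ``n_bins``, the whole transcript
    is one region.
    """
    if profile_ip.transcript_id != profile_ctrl.transcript_id:
        raise ValueError("profiles are on different transcripts")
    if profile_ip.normalization != profile_ctrl.normalization:
        raise ValueError("profiles use different normalization modes")
    if profile_ip.length != profile_ctrl.length:
        raise ValueError("profile length mismatch")

    def fold(lo: int, hi: int) -> float:
        a = float(profile_ip.values[lo:hi].sum())
        b = float(profile_ctrl.values[lo:hi].sum())
        return (a + pseudocount) / (b + pseudocount)

    if regions is not None:
        return {name: fold(s, e) for name, (s, e) in regions.items()}
    if n_bins is not None:
        edges = bin_edges(profile_ip.length, n_bins)
        return {f"bin_{b + 1}": fold(edges[b], edges[b + 1]) for b in range(n_bins)}
    return {"transcript": fold(0, profile_ip.length)}


# ---------------------------------------------------------------------------
# Export

def write_bedgraph(profile: PositionalProfile, path: str | Path) -> None:
    """Transcript-space bedGraph (runs of equal value merged)."""
    v = profile.values
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{profile.transcript_id}"\n')
        i = 0
        while i < v.size:
            j = i
            while j + 1 < v.size and v[j + 1] == v[i]:
                j += 1
            if v[i] != 0:
                fh.write(f"{profile.transcript_id}\t{i}\t{j + 1}\t{v[i]:g}\n")
            i = j + 1


def write_profile_tsv(profile: PositionalProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tposition\tvalue\n")
        for i, val in enumerate(profile.values):
            fh.write(f"{profile.transcript_id}\t{i}\t{val:g}\n")


def write_bin_matrix(bin_vectors: Sequence[BinVector], path: str | Path) -> None:
    import pandas as pd

    n = bin_vectors[0].bins.size if bin_vectors else 10
    df = pd.DataFrame(
        [bv.bins for bv in bin_vectors],
        index=[bv.transcript_id for bv in bin_vectors],
        columns=[f"bin_{i + 1}" for i in range(n)],
    )
    df.index.name = "gene"
    df.to_csv(path, sep="\t")
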