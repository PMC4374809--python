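"""piRNA target-site prediction and positional enrichment.

A target site is an ungapped, end-to-end antisense match of a 21-nt piRNA
to a transcript window: position p is a hit when the Hamming distance
between transcript[p:p+21] and the reverse complement of the piRNA is at
most ``max_mm`` (default 3).  N bases count as mismatches.  Sites are then
assigned to the 5' or 3' half of the transcript by their midpoint, and
site-position bias of a gene cluster is tested against a background set
with Fisher's exact test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats
from .reference import (FIVE_PRIME, THREE_PRIME, PiRNA, TranscriptModel,
                        position_in_half, revcomp)

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_PIRNA_LEN = 21


@dataclass(frozen=True)
class TargetSitePrediction:
    pirna_id: str
    transcript_id: str
    start: int
    mismatches: int
    half: str

    @property
    def end(self) -> int:
        return self.start + _PIRNA_LEN

    @property
    def midpoint(self) -> int:
        return self.start + _PIRNA_LEN // 2


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def predict_sites(pirnas: Sequence[PiRNA], transcripts: Sequence[TranscriptModel],
                  max_mm: int = 3, strict: bool = True) -> list[TargetSitePrediction]:
    """Scan every transcript position for antisense piRNA matches.

    All positions p with p + 21 <= L are tested for every piRNA;
    overlapping hits are all reported.  The site's half assignment uses its
    midpoint under the transcript's deterministic half rule.
    """
    out: list[TargetSitePrediction] = []
    queries = []
    for q in pirnas:
        if len(q.sequence) != _PIRNA_LEN:
            if strict:
                raise ValueError(f"piRNA {q.id}: length {len(q.sequence)} != {_PIRNA_LEN}")
            continue
        queries.append((q.id, _encode(revcomp(q.sequence))))
    for t in transcripts:
        L = t.spliced_length
        if L < _PIRNA_LEN:
            continue
        enc = _encode(t.sequence)
        # N in the transcript can never match (N is not a base in the query
        # after revcomp of ACGT; any N counts as mismatch via inequality,
        # but query N vs transcript N would spuriously "match": force it.
        windows = np.lib.stride_tricks.sliding_window_view(enc, _PIRNA_LEN)
        t_is_n = windows == ord("N")
        for pid, qenc in queries:
            mm = (windows != qenc[None, :]).sum(axis=1)
            if (qenc == ord("N")).any():
                mm = ((windows != qenc[None, :]) | (qenc[None, :] == ord("N"))
                      | t_is_n).sum(axis=1)
            elif t_is_n.any():
                mm = ((windows != qenc[None, :]) | t_is_n).sum(axis=1)
            for p in np.nonzero(mm <= max_mm)[0]:
                p = int(p)
                out.append(TargetSitePrediction(
                    pirna_id=pid, transcript_id=t.id, start=p,
                    mismatches=int(mm[p]),
                    half=position_in_half(t, p + _PIRNA_LEN // 2)))
    return out


@dataclass(frozen=True)
class HalfEnrichment:
    """3'-vs-5' site-position bias of a gene cluster against background.

    The 2x2 table is (cluster 3', cluster 5'; background 3', background 5')
    site counts.  ``log2_enrichment`` uses a 0.5 pseudocount per cell for
    display; the Fisher p is computed on the raw counts.  A within-cluster
    binomial against 0.5 is reported as a secondary statistic.
    """

    cluster_id: str | int
    a: int  # cluster sites in 3' half
    b: int  # cluster sites in 5' half
    c: int  # background sites in 3' half
    d: int  # background sites in 5' half
    log2_enrichment: float
    p: float
    p_binomial: float


def half_enrichment(predictions: Iterable[TargetSitePrediction],
                    cluster_genes: Iterable[str],
                    background_genes: Iterable[str],
                    cluster_id: str | int = "cluster",
                    alternative: str = stats.GREATER,
                    pseudocount: float = 0.5) -> HalfEnrichment:
    """Test whether cluster genes' predicted sites are 3'-biased.

    ``alternative='greater'`` (default) asks for 3' bias relative to the
    background; pass ``'less'`` for the mirrored 5'-bias question.
    """
    cluster = set(cluster_genes)
    background = set(background_genes)
    if not cluster:
        raise ValueError("empty cluster gene set")
    if cluster & background:
        raise ValueError("cluster and background gene sets overlap")
    a = b = c = d = 0
    for s in predictions:
        if s.transcript_id in cluster:
            if s.half == THREE_PRIME:
                a += 1
            else:
                b += 1
        elif s.transcript_id in background:
            if s.half == THREE_PRIME:
                c += 1
            else:
                d += 1
    log2_enr = math.log2(((a + pseudocount) / (b + pseudocount))
                         / ((c + pseudocount) / (d + pseudocount)))
    p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    # secondary: within-cluster binomial sign test against 0.5
    from scipy.stats import binomtest
    n = a + b
    if n > 0:
        alt = {stats.GREATER: "greater", stats.LESS: "less",
               stats.TWO_SIDED: "two-sided"}[alternative]
        p_binom = float(binomtest(a, n, 0.5, alternative=alt).pvalue)
    else:
        p_binom = 1.0
    return HalfEnrichment(cluster_id, a, b, c, d, log2_enr, p, p_binom)


@dataclass
class LevelChangeResult:
    """Per-gene 22G level change between two conditions plus a paired test."""

    table: pd.DataFrame  # gene, count_mut, count_wt, log2_ratio
    wilcoxon: stats.SignedRankResult

    @property
    def median_log2_ratio(self) -> float:
        return float(self.table["log2_ratio"].median())


def per_gene_level_change(counts_mut: Mapping[str, float],
                          counts_wt: Mapping[str, float],
                          library_sizes: tuple[float, float],
                          pseudocount: float = 1.0,
                          alternative: str = stats.LESS) -> LevelChangeResult:
    """Library-size-normalized per-gene log2 ratios and a paired Wilcoxon test.

    ``pseudocount`` is in reads per million.  The default alternative
    ('less') asks whether the mutant lost 22Gs relative to wild type.
    """
    if set(counts_mut) != set(counts_wt):
        raise ValueError("gene universes differ between conditions")
    lib_mut, lib_wt = library_sizes
    genes = sorted(counts_mut)
    mut_rpm = np.array([counts_mut[g] * 1e6 / lib_mut for g in genes])
    wt_rpm = np.array([counts_wt[g] * 1e6 / lib_wt for g in genes])
    log2_ratio = np.log2((mut_rpm + pseudocount) / (wt_rpm + pseudocount))
    table = pd.DataFrame({
        "gene": genes,
        "count_mut": [counts_mut[g] for g in genes],
        "count_wt": [counts_wt[g] for g in genes],
        "mut_rpm": mut_rpm, "wt_rpm": wt_rpm,
        "log2_ratio": log2_ratio,
    })
    test = stats.wilcoxon_signed_rank(mut_rpm - wt_rpm, alternative=alternative)
    return LevelChangeResult(table=table, wilcoxon=test)


def boxplot_summary(level_change: LevelChangeResult,
                    assignments: Mapping[str, int]) -> pd.DataFrame:
    """Per-cluster quartiles and 1.5-IQR whiskers of the log2 ratios."""
    df = level_change.table.copy()
    df["cluster"] = df["gene"].map(assignments)
    rows = []
    for cid, grp in df.dropna(subset=["cluster"]).groupby("cluster"):
        v = grp["log2_ratio"].to_numpy()
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        lo = v[v >= q1 - 1.5 * iqr].min()
        hi = v[v <= q3 + 1.5 * iqr].max()
        rows.append({"cluster": int(cid), "n_genes": len(v), "q1": q1,
                     "median": med, "q3": q3, "whisker_low": lo,
                     "whisker_high": hi})
    return pd.DataFrame(rows)


def write_predictions_tsv(predictions: Iterable[TargetSitePrediction],
                          path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pirna_id\ttranscript_id\tstart\tmismatches\thalf\n")
        for s in predictions:
            fh.write(f"{s.pirna_id}\t{s.transcript_id}\t{s.start}"
                     f"\t{s.mismatches}\t{s.half}\n")
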