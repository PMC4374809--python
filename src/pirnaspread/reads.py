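"""Small-RNA read handling: classification, exact placement on reference
transcripts, filtering and normalization factors.

Reads are assumed adapter-trimmed and error-free with respect to their
source (the simulator guarantees this); placement is exact string matching
of the read and of its reverse complement against the supplied reference
set.  Uniqueness (``n_loci``) is defined over that reference set only, not
over a genome.
"""

from __future__ import annotations

import gzip
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .reference import TranscriptModel, revcomp

SENSE = "sense"
ANTISENSE = "antisense"


@dataclass(frozen=True)
class SmallRNARead:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.id}: empty sequence")
        seq = self.sequence.upper().replace("U", "T")
        if set(seq) - set("ACGTN"):
            raise ValueError(f"read {self.id}: invalid characters")
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def first_nt(self) -> str:
        return self.sequence[0]


@dataclass
class ReadSet:
    """A library of small-RNA reads, optionally with simulator provenance.

    ``provenance`` (when present) is a DataFrame indexed like the reads with
    columns such as source_id / region / position recorded by the generator;
    analysis code never reads it, tests do.
    """

    reads: list[SmallRNARead]
    provenance: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    @classmethod
    def from_fastq(cls, path: str | Path) -> "ReadSet":
        reads = []
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "rt") as fh:
            while True:
                header = fh.readline()
                if not header:
                    break
                seq = fh.readline().strip()
                fh.readline()
                fh.readline()
                reads.append(SmallRNARead(header.strip().lstrip("@").split()[0], seq))
        return cls(reads=reads)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReadSet":
        from Bio import SeqIO
        return cls(reads=[SmallRNARead(r.id, str(r.seq))
                          for r in SeqIO.parse(str(path), "fasta")])

    def write_fastq(self, path: str | Path, quality_char: str = "I") -> None:
        with open(path, "w") as fh:
            for r in self.reads:
                fh.write(f"@{r.id}\n{r.sequence}\n+\n{quality_char * r.length}\n")


@dataclass(frozen=True)
class AlignmentHit:
    """One exact placement of a read on a transcript (spliced coordinates).

    ``start``/``end`` delimit the covered interval (0-based half-open) on
    the transcript's sense strand regardless of orientation.  The read's
    length and 5' nucleotide are carried so hits can be class-filtered
    without a side lookup.
    """

    read_id: str
    transcript_id: str
    start: int
    end: int
    orientation: str
    n_loci: int
    read_first_nt: str = "N"

    def __post_init__(self) -> None:
        if self.orientation not in (SENSE, ANTISENSE):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime_position(self) -> int:
        """Transcript position of the read's 5' end.

        An antisense read runs 3'->5' in transcript coordinates, so its 5'
        end sits at the right edge of the covered interval.
        """
        return self.end - 1 if self.orientation == ANTISENSE else self.start


def classify_22g(read: SmallRNARead,
                 length_range: tuple[int, int] = (21, 23),
                 first_nt: str = "G") -> bool:
    """True iff the read belongs to the 22G class (~22 nt, 5' G).

    The class is named for its characteristic length and 5' nucleotide;
    field practice tolerates +/-1 nt, hence the default 21-23 range.  Both
    bounds and the 5' nucleotide are configurable.
    """
    if not read.sequence:
        raise ValueError("empty read")
    lo, hi = length_range
    return lo <= read.length <= hi and read.first_nt == first_nt.upper()


def align_exact(reads: ReadSet | Sequence[SmallRNARead],
                refs: Sequence[TranscriptModel]) -> list[AlignmentHit]:
    """Report every exact occurrence of each read, sense and antisense.

    ``n_loci`` is the total number of placements of the read's sequence
    across the whole reference set (both orientations), so unique-mapper
    filtering is a simple ``n_loci == 1`` check downstream.
    """
    read_list = list(reads.reads if isinstance(reads, ReadSet) else reads)
    if not read_list:
        return []
    max_ref = max(r.spliced_length for r in refs) if refs else 0
    lengths = sorted({r.length for r in read_list})
    if lengths and lengths[0] > max_ref:
        raise ValueError("every read is longer than every reference")

    # query map: substring-to-look-for -> [(read_sequence, orientation)]
    qmap: dict[str, list[tuple[str, str]]] = defaultdict(list)
    for seq in {r.sequence for r in read_list}:
        qmap[seq].append((seq, SENSE))
        rc = revcomp(seq)
        qmap[rc].append((seq, ANTISENSE))

    # one scan of all reference substrings at the read lengths present
    occ: dict[str, list[tuple[str, int, str]]] = defaultdict(list)
    for ref in refs:
        s = ref.sequence
        L = len(s)
        for k in lengths:
            for i in range(L - k + 1):
                sub = s[i:i + k]
                hits = qmap.get(sub)
                if hits:
                    for read_seq, orient in hits:
                        occ[read_seq].append((ref.id, i, orient))

    out: list[AlignmentHit] = []
    for r in read_list:
        placements = occ.get(r.sequence, ())
        n = len(placements)
        for tid, pos, orient in placements:
            out.append(AlignmentHit(
                read_id=r.id, transcript_id=tid, start=pos, end=pos + r.length,
                orientation=orient, n_loci=n, read_first_nt=r.first_nt))
    return out


def filter_hits(hits: Iterable[AlignmentHit],
                unique_only: bool = True,
                orientation: str | None = ANTISENSE,
                class_filter: bool = True,
                length_range: tuple[int, int] = (21, 23),
                first_nt: str = "G",
                log: dict | None = None) -> list[AlignmentHit]:
    """Keep unique, antisense, 22G-class hits (each stage configurable).

    Idempotent: filtering a filtered list changes nothing.  If ``log`` is
    given, per-stage removal counts are recorded into it.
    """
    hits = list(hits)
    n0 = len(hits)
    if unique_only:
        hits = [h for h in hits if h.n_loci == 1]
    n1 = len(hits)
    if orientation is not None:
        hits = [h for h in hits if h.orientation == orientation]
    n2 = len(hits)
    if class_filter:
        lo, hi = length_range
        fnt = first_nt.upper()
        hits = [h for h in hits
                if lo <= h.length <= hi and h.read_first_nt == fnt]
    if log is not None:
        log.update({
            "input": n0,
            "removed_multi_locus": n0 - n1,
            "removed_orientation": n1 - n2,
            "removed_class": n2 - len(hits),
            "output": len(hits),
        })
    return hits


@dataclass(frozen=True)
class NormalizationFactors:
    """Scaling denominators for profile values.

    ``per_his58`` divides by reads matching the normalizer segment (shared
    across the reporter constructs), ``per_million`` by library size in
    millions, ``raw`` leaves counts untouched.
    """

    library_total: int
    his58_total: int = 0
    mode: str = "raw"

    MODES = ("raw", "per_million", "per_his58")

    def __post_init__(self) -> None:
        if self.mode not in self.MODES:
            raise ValueError(f"unknown normalization mode {self.mode!r}")
        if self.his58_total > self.library_total:
            raise ValueError("his58_total cannot exceed library_total")
        if self.mode == "per_his58" and self.his58_total <= 0:
            raise ValueError("per_his58 requested but no normalizer reads")
        if self.mode == "per_million" and self.library_total <= 0:
            raise ValueError("per_million requested but library is empty")

    @property
    def denominator(self) -> float:
        if self.mode == "raw":
            return 1.0
        if self.mode == "per_million":
            return self.library_total / 1e6
        return float(self.his58_total)


def normalization_factors(hits: Iterable[AlignmentHit],
                          library_total: int,
                          normalizer: tuple[str, tuple[int, int]] | None = None,
                          mode: str = "raw") -> NormalizationFactors:
    """Count normalizer-segment reads and package scaling denominators.

    A read counts toward the normalizer when one of its placements is fully
    contained in the normalizer segment, in either orientation and at any
    length; containment avoids double-counting edge overlaps.  Each read id
    counts once.
    """
    his58 = 0
    if normalizer is not None:
        tid, (seg_start, seg_end) = normalizer
        seen: set[str] = set()
        for h in hits:
            if (h.transcript_id == tid and h.start >= seg_start
                    and h.end <= seg_end and h.read_id not in seen):
                seen.add(h.read_id)
        his58 = len(seen)
    return NormalizationFactors(library_total=library_total,
                                his58_total=his58, mode=mode)


# ---------------------------------------------------------------------------
# External alignment interchange: 6-column TSV
# (read_id, transcript_id, start, end, strand, n_loci); 0-based half-open,
# strand '+' = sense / '-' = antisense relative to the transcript.

def write_alignment_tsv(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\ttranscript_id\tstart\tend\tstrand\tn_loci\n")
        for h in hits:
            strand = "+" if h.orientation == SENSE else "-"
            fh.write(f"{h.read_id}\t{h.transcript_id}\t{h.start}\t{h.end}"
                     f"\t{strand}\t{h.n_loci}\n")


def load_alignment_tsv(path: str | Path,
                       reads: ReadSet | None = None) -> list[AlignmentHit]:
    """Ingest externally produced alignments.

    If the originating reads are supplied, each hit's 5' nucleotide is
    recovered from the read sequence so class filtering stays possible.
    """
    seqs = {r.id: r for r in reads} if reads is not None else {}
    out = []
    df = pd.read_csv(path, sep="\t")
    for row in df.itertuples(index=False):
        first = seqs[row.read_id].first_nt if row.read_id in seqs else "N"
        out.append(AlignmentHit(
            read_id=str(row.read_id), transcript_id=str(row.transcript_id),
            start=int(row.start), end=int(row.end),
            orientation=SENSE if row.strand == "+" else ANTISENSE,
            n_loci=int(row.n_loci), read_first_nt=first))
    return out
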