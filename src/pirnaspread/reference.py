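"""Reference sequences and coordinate conventions.

Everything downstream (profiles, bins, target sites) lives on the *spliced*
transcript: 0-based, half-open coordinates with the start of the transcript
(start codon for the reporter constructs) at 0, read 5'->3' along the mRNA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

VALID_ALPHABET = set("ACGTN")

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"


class ReferenceError(ValueError):
    """Malformed reference input (duplicate ids, bad annotation, empty file)."""


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class TranscriptModel:
    """A spliced transcript and the exon structure it came from.

    ``exons`` are genomic intervals (0-based, half-open) on the parent
    sequence record; ``sequence`` is the spliced mRNA 5'->3'.  For a
    minus-strand transcript the spliced sequence is the reverse complement
    of the concatenated exon sequence.  ``genomic_sequence`` (the full
    parent span) is retained when known so the model can be re-serialized.
    """

    id: str
    strand: str
    exons: list[tuple[int, int]]
    sequence: str
    genomic_sequence: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ReferenceError(f"strand must be + or -, got {self.strand!r}")
        self.sequence = self.sequence.upper().replace("U", "T")
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise ReferenceError(f"{self.id}: invalid characters {sorted(bad)}")
        ex = sorted(self.exons)
        if ex != list(self.exons):
            raise ReferenceError(f"{self.id}: exons must be sorted")
        for (s0, e0), (s1, e1) in zip(ex, ex[1:]):
            if s1 < e0:
                raise ReferenceError(f"{self.id}: overlapping exons")
        for s, e in ex:
            if not (0 <= s < e):
                raise ReferenceError(f"{self.id}: invalid exon interval ({s},{e})")
        if sum(e - s for s, e in ex) != len(self.sequence):
            raise ReferenceError(
                f"{self.id}: exon lengths ({sum(e - s for s, e in ex)}) do not "
                f"match spliced sequence length ({len(self.sequence)})"
            )

    @property
    def spliced_length(self) -> int:
        return len(self.sequence)

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Genomic gaps between consecutive exons."""
        return [
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])
        ]

    @property
    def genomic_span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def spliced_to_genomic(self, pos: int) -> int:
        """Map a spliced-transcript position to its genomic coordinate."""
        if not 0 <= pos < self.spliced_length:
            raise ReferenceError(f"{self.id}: spliced position {pos} out of range")
        # walk exons in transcription order
        p = pos if self.strand == "+" else self.spliced_length - 1 - pos
        for s, e in self.exons:
            if p < e - s:
                return s + p
            p -= e - s
        raise AssertionError("unreachable")

    @classmethod
    def from_sequence(cls, id: str, sequence: str, strand: str = "+") -> "TranscriptModel":
        """Single-exon transcript spanning the whole record."""
        seq = sequence.upper().replace("U", "T")
        return cls(id=id, strand=strand, exons=[(0, len(seq))], sequence=seq,
                   genomic_sequence=seq)


@dataclass(frozen=True)
class PiRNA:
    """A 21-nt Piwi-interacting RNA; stored in DNA alphabet (U -> T)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper().replace("U", "T"))

    def validate(self, strict: bool = False) -> None:
        if len(self.sequence) != 21:
            raise ReferenceError(f"piRNA {self.id}: length {len(self.sequence)} != 21")
        if not self.sequence.startswith("T"):
            msg = f"piRNA {self.id}: 5' nucleotide is {self.sequence[0]}, expected U"
            if strict:
                raise ReferenceError(msg)
            warnings.warn(msg, stacklevel=2)


SEGMENT_ROLES = {"coding", "normalizer", "target_site", "utr", "linker"}


@dataclass(frozen=True)
class Segment:
    name: str
    role: str
    sequence: str
    pirna_id: str | None = None

    def __post_init__(self) -> None:
        if self.role not in SEGMENT_ROLES:
            raise ReferenceError(f"unknown segment role {self.role!r}")
        if not self.sequence:
            raise ReferenceError(f"segment {self.name!r} has empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper().replace("U", "T"))


@dataclass
class TransgeneConstruct:
    """A single-copy reporter transgene built from named segments.

    Segment coordinates tile the construct without gaps; position 0 is the
    construct start (the start codon in the reporter designs).  The derived
    ``transcript`` is single-exon: the constructs are profiled on their
    spliced/mature form.
    """

    id: str
    segments: list[Segment]
    intervals: dict[str, tuple[int, int]] = field(init=False)
    target_site_interval: tuple[int, int] | None = field(init=False)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ReferenceError(f"{self.id}: empty segment list")
        self.intervals = {}
        offset = 0
        sites: dict[str, tuple[int, int]] = {}
        for seg in self.segments:
            iv = (offset, offset + len(seg.sequence))
            if seg.name in self.intervals:
                raise ReferenceError(f"{self.id}: duplicate segment name {seg.name!r}")
            self.intervals[seg.name] = iv
            if seg.role == "target_site":
                key = seg.pirna_id or seg.name
                if key in sites:
                    raise ReferenceError(
                        f"{self.id}: two target_site segments for piRNA {key!r}")
                sites[key] = iv
            offset += len(seg.sequence)
        self.target_site_interval = next(iter(sites.values())) if sites else None

    @property
    def sequence(self) -> str:
        return "".join(seg.sequence for seg in self.segments)

    @property
    def length(self) -> int:
        return sum(len(s.sequence) for s in self.segments)

    def segment_at(self, pos: int) -> Segment:
        """Segment containing spliced position ``pos``."""
        if not 0 <= pos < self.length:
            raise ReferenceError(f"position {pos} outside construct {self.id}")
        for seg in self.segments:
            s, e = self.intervals[seg.name]
            if s <= pos < e:
                return seg
        raise AssertionError("unreachable: segments tile the construct")

    def segment_interval(self, name: str) -> tuple[int, int]:
        return self.intervals[name]

    @property
    def transcript(self) -> TranscriptModel:
        return TranscriptModel.from_sequence(self.id, self.sequence)


def build_transgene(construct_id: str, segments: Sequence[Segment]) -> TransgeneConstruct:
    return TransgeneConstruct(id=construct_id, segments=list(segments))


def position_in_half(t: TranscriptModel, pos: int) -> str:
    """Assign a spliced position to the 5' or 3' half of the transcript.

    Positions strictly below floor(L/2) are 5'; the midpoint of an
    odd-length transcript falls 3'.  This makes the partition deterministic
    and symmetric to within one nucleotide.
    """
    if not 0 <= pos < t.spliced_length:
        raise ReferenceError(
            f"position {pos} outside transcript {t.id} (length {t.spliced_length})")
    return FIVE_PRIME if pos < t.spliced_length // 2 else THREE_PRIME


# ---------------------------------------------------------------------------
# I/O

def load_pirnas(fasta: str | Path, strict: bool = False) -> list[PiRNA]:
    records = list(SeqIO.parse(str(fasta), "fasta"))
    if not records:
        raise ReferenceError(f"{fasta}: empty FASTA")
    out = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ReferenceError(f"duplicate piRNA id {rec.id!r}")
        seen.add(rec.id)
        p = PiRNA(rec.id, str(rec.seq))
        p.validate(strict=strict)
        out.append(p)
    return out


def _parse_bed12(path: Path) -> dict[str, dict]:
    out: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ReferenceError(f"{path}: BED12 needs 12 columns, got {len(f)}")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != int(f[9]) or len(starts) != int(f[9]):
                raise ReferenceError(f"{path}: blockCount mismatch for {name}")
            exons = [(start + st, start + st + sz) for st, sz in zip(starts, sizes)]
            if name in out:
                raise ReferenceError(f"duplicate transcript id {name!r} in annotation")
            out[name] = {"seqid": chrom, "strand": strand, "exons": exons}
    return out


def _parse_gff3(path: Path) -> dict[str, dict]:
    out: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ReferenceError(f"{path}: GFF3 needs 9 columns, got {len(f)}")
            if f[2].lower() != "exon":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            parent = attrs.get("Parent") or attrs.get("ID")
            if parent is None:
                raise ReferenceError(f"{path}: exon without Parent attribute")
            rec = out.setdefault(
                parent, {"seqid": f[0], "strand": f[6], "exons": []})
            rec["exons"].append((int(f[3]) - 1, int(f[4])))  # GFF is 1-based closed
    for rec in out.values():
        rec["exons"].sort()
    return out


def _sniff_annotation(path: Path) -> str:
    kinds = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) == 9 and f[3].isdigit() and f[4].isdigit():
                kinds.add("gff3")
            elif len(f) >= 12:
                kinds.add("bed12")
            else:
                raise ReferenceError(f"{path}: unrecognized annotation line: {line[:60]}")
    if len(kinds) != 1:
        raise ReferenceError(f"{path}: mixed or unrecognizable annotation dialects")
    return kinds.pop()


def load_references(fasta: str | Path,
                    annotation: str | Path | None = None) -> list[TranscriptModel]:
    """Load transcript models from FASTA, optionally spliced via GFF3/BED12.

    Without annotation each FASTA record becomes a single-exon transcript.
    With annotation, each annotated transcript is spliced out of the FASTA
    record named by its seqid/chrom field.
    """
    records = {}
    for rec in SeqIO.parse(str(fasta), "fasta"):
        if rec.id in records:
            raise ReferenceError(f"duplicate sequence id {rec.id!r} in {fasta}")
        records[rec.id] = str(rec.seq).upper().replace("U", "T")
    if not records:
        raise ReferenceError(f"{fasta}: empty FASTA")

    if annotation is None:
        return [TranscriptModel.from_sequence(rid, seq) for rid, seq in records.items()]

    path = Path(annotation)
    dialect = _sniff_annotation(path)
    ann = _parse_bed12(path) if dialect == "bed12" else _parse_gff3(path)
    if not ann:
        raise ReferenceError(f"{path}: no transcripts in annotation")
    models = []
    for tid, rec in ann.items():
        if rec["seqid"] not in records:
            raise ReferenceError(f"transcript {tid!r}: no sequence for {rec['seqid']!r}")
        genomic = records[rec["seqid"]]
        for s, e in rec["exons"]:
            if e > len(genomic):
                raise ReferenceError(
                    f"transcript {tid!r}: exon ({s},{e}) exceeds sequence "
                    f"length {len(genomic)}")
        spliced = "".join(genomic[s:e] for s, e in rec["exons"])
        if rec["strand"] == "-":
            spliced = revcomp(spliced)
        models.append(TranscriptModel(
            id=tid, strand=rec["strand"], exons=rec["exons"], sequence=spliced,
            genomic_sequence=genomic))
    return models


def write_references(models: Iterable[TranscriptModel], fasta: str | Path,
                     bed12: str | Path) -> None:
    """Serialize models as genomic FASTA plus BED12 exon structure."""
    models = list(models)
    with open(fasta, "w") as fh:
        for m in models:
            if m.genomic_sequence is None:
                raise ReferenceError(f"{m.id}: genomic sequence unknown, cannot write")
            fh.write(f">{m.id}_span\n{m.genomic_sequence}\n")
    with open(bed12, "w") as fh:
        for m in models:
            start, end = m.genomic_span
            sizes = ",".join(str(e - s) for s, e in m.exons)
            starts = ",".join(str(s - start) for s, e in m.exons)
            fh.write("\t".join([
                f"{m.id}_span", str(start), str(end), m.id, "0", m.strand,
                str(start), str(end), "0", str(len(m.exons)), sizes, starts,
            ]) + "\n")


def load_transgene_tsv(path: str | Path) -> TransgeneConstruct:
    """Build a construct from a TSV segment table (name, role, sequence[, pirna_id])."""
    segs = []
    construct_id = Path(path).stem
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ReferenceError(f"{path}: segment line needs >=3 columns")
            segs.append(Segment(f[0], f[1], f[2], f[3] if len(f) > 3 else None))
    return build_transgene(construct_id, segs)
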