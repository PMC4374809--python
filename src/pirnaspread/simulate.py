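"""Genotype-conditional synthetic small-RNA read generation.

The generator emulates the read populations the analysis is built to
detect, with ground truth attached:

* a piRNA sensor transgene (GFP :: his-58 :: 21U target site +/- 50 bp ::
  tbb-2 3'UTR) producing *proximal* (secondary) antisense 22G reads within
  a window of the piRNA target site when the piRNA pathway is active, and
  *distal* (tertiary) reads over the rest of the construct only when the
  nuclear RNAi pathway is additionally intact;
* a bicistronic operon reporter (mCherry :: linker :: GFP :: par-5 3'UTR)
  for trans-silencing and RNAi-feeding scenarios;
* a genome-like panel of genes in which one class carries 3'-half piRNA
  sites and loses its 5' reads in nuclear-RNAi mutants, a mirrored class
  carries 5'-half sites, and the rest show genotype-insensitive 22G
  patterns of several distinct shapes.

Reads are exact reverse-complement substrings of their source transcript
(antisense), anchored at template-C positions so every antisense read
starts with G; read counts per region are Poisson with mean
``rate * region_length * depth``.  Fixed seed gives byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .reads import ANTISENSE, SENSE, ReadSet, SmallRNARead
from .reference import (PiRNA, Segment, TranscriptModel, TransgeneConstruct,
                        build_transgene, revcomp)

# internal constant seed for reference sequences: constructs and the 21U
# query are part of the reference, not of any one simulated library
_REFERENCE_SEED = 424243
_MAX_READ_LEN = 23


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class GenotypeSpec:
    """Which siRNA tiers a genotype can produce.

    ``secondary_active`` is false in genotypes lacking piRNA recognition or
    22G biogenesis (prg-1, mut-16, rrf-1;ego-1, drh-3); ``tertiary_active``
    is false in nuclear-RNAi mutants (hrde-1, nrde-1, nrde-4) and, because
    tertiary production requires the secondary tier, whenever
    ``secondary_active`` is false.
    """

    name: str
    secondary_active: bool
    tertiary_active: bool

    def __post_init__(self) -> None:
        if self.tertiary_active and not self.secondary_active:
            raise SimulationError(
                f"{self.name}: tertiary_active requires secondary_active")


GENOTYPES: dict[str, GenotypeSpec] = {
    "wild_type": GenotypeSpec("wild_type", True, True),
    "prg-1": GenotypeSpec("prg-1", False, False),
    "mut-16": GenotypeSpec("mut-16", False, False),
    "rrf-1;ego-1": GenotypeSpec("rrf-1;ego-1", False, False),
    "drh-3": GenotypeSpec("drh-3", False, False),
    "hrde-1": GenotypeSpec("hrde-1", True, False),
    "nrde-1": GenotypeSpec("nrde-1", True, False),
    "nrde-4": GenotypeSpec("nrde-4", True, False),
}


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    depth: int = 100_000
    lambda_proximal: float = 1.5e-5   # antisense reads / nt / unit depth
    lambda_distal: float = 8e-6
    lambda_background: float = 1e-9
    proximal_window: int = 200
    read_length_distribution: tuple[tuple[int, float], ...] = (
        (21, 0.15), (22, 0.70), (23, 0.15))
    his58_rate: float = 2000.0        # expected normalizer reads
    ip_fold: float = 10.0
    n_genes: int = 300
    fraction_cluster6_like: float = 0.5
    fraction_cluster1_like: float = 0.2
    untargeted_expression_fold: float = 2.0

    def __post_init__(self) -> None:
        for name in ("lambda_proximal", "lambda_distal", "lambda_background",
                     "his58_rate"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        probs = [p for _, p in self.read_length_distribution]
        if abs(sum(probs) - 1.0) > 1e-9 or any(p < 0 for p in probs):
            raise SimulationError("read length probabilities must sum to 1")
        if self.proximal_window < 0:
            raise SimulationError("proximal_window must be >= 0")
        if self.fraction_cluster6_like + self.fraction_cluster1_like > 1:
            raise SimulationError("class fractions sum to more than 1")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([l for l, _ in self.read_length_distribution])

    @property
    def length_probs(self) -> np.ndarray:
        return np.array([p for _, p in self.read_length_distribution])

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["read_length_distribution"] = dict(self.read_length_distribution)
        return d


@dataclass
class TruthTable:
    """Ground truth attached to a simulated read set or panel."""

    transcripts: pd.DataFrame
    genotype: str | None = None
    config: SimConfig | None = None


# ---------------------------------------------------------------------------
# Reference construction

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n).tobytes().decode()


def sensor_pirna() -> PiRNA:
    """The simulator's 21U query (5'-U, 21 nt), fixed across all seeds."""
    rng = np.random.default_rng(_REFERENCE_SEED)
    return PiRNA("21UR-sim-1", "T" + _random_seq(rng, 20))


def make_sensor_construct() -> TransgeneConstruct:
    """GFP :: his-58 :: (21U site +/- 50 bp) :: tbb-2 3'UTR, 1561 nt."""
    rng = np.random.default_rng(_REFERENCE_SEED + 1)
    site_seq = revcomp(sensor_pirna().sequence)
    segments = [
        Segment("gfp", "coding", _random_seq(rng, 870)),
        Segment("his-58", "normalizer", _random_seq(rng, 370)),
        Segment("21UR-1_site", "target_site",
                _random_seq(rng, 50) + site_seq + _random_seq(rng, 50),
                pirna_id="21UR-sim-1"),
        Segment("tbb-2_utr", "utr", _random_seq(rng, 200)),
    ]
    return build_transgene("piRNA_sensor", segments)


def sensor_reference_set(construct: TransgeneConstruct | None = None,
                         ) -> list[TranscriptModel]:
    """Sensor construct plus an endogenous his-58 locus.

    The normalizer segment is an endogenous histone gene that exists
    outside the transgene, so reads matching it place at two loci and are
    removed by unique-match filtering — only reads unique to the construct
    contribute to its antisense profile, while the duplicate-locus reads
    still count for his-58 normalization.
    """
    if construct is None:
        construct = make_sensor_construct()
    his_lo, his_hi = construct.segment_interval("his-58")
    endogenous = TranscriptModel.from_sequence(
        "his-58_endogenous", construct.sequence[his_lo:his_hi])
    return [construct.transcript, endogenous]


def make_operon_construct() -> TransgeneConstruct:
    """mCherry :: gpd-2 linker :: GFP :: par-5 3'UTR bicistronic reporter."""
    rng = np.random.default_rng(_REFERENCE_SEED + 2)
    segments = [
        Segment("mcherry", "coding", _random_seq(rng, 711)),
        Segment("gpd-2_linker", "linker", _random_seq(rng, 100)),
        Segment("gfp", "coding", _random_seq(rng, 870)),
        Segment("par-5_utr", "utr", _random_seq(rng, 200)),
    ]
    return build_transgene("operon", segments)


# ---------------------------------------------------------------------------
# Read emission primitives

def _c_positions(seq: str) -> np.ndarray:
    return np.nonzero(np.frombuffer(seq.encode(), dtype=np.uint8) == ord("C"))[0]


def _emit_antisense(rng: np.random.Generator, seq: str,
                    intervals: Sequence[tuple[int, int]], n: int,
                    cfg: SimConfig, source_id: str, region: str,
                    prefix: str, records: list, rows: list) -> None:
    """Emit ``n`` antisense reads whose 5' ends fall in ``intervals``.

    5'-end positions are drawn uniformly from template-C positions inside
    the intervals (so every read starts with G); positions too close to
    the transcript start to fit a full-length read are excluded.
    """
    if n == 0:
        return
    cpos = _c_positions(seq)
    mask = np.zeros(len(seq), dtype=bool)
    for lo, hi in intervals:
        mask[max(0, lo):max(0, hi)] = True
    candidates = cpos[(mask[cpos]) & (cpos >= _MAX_READ_LEN - 1)]
    if candidates.size == 0:
        raise SimulationError(
            f"{source_id}: no template-C position available in window(s) "
            f"{list(intervals)} for {region} reads")
    p5s = rng.choice(candidates, size=n)
    lens = rng.choice(cfg.lengths, size=n, p=cfg.length_probs)
    for i, (p5, ln) in enumerate(zip(p5s, lens)):
        p5, ln = int(p5), int(ln)
        start = p5 - ln + 1
        rid = f"{prefix}_{region}_{i:06d}"
        records.append(SmallRNARead(rid, revcomp(seq[start:p5 + 1])))
        rows.append((rid, source_id, region, p5, ln, ANTISENSE))


def _emit_normalizer(rng: np.random.Generator, seq: str,
                     segment: tuple[int, int], n: int, cfg: SimConfig,
                     source_id: str, prefix: str, records: list,
                     rows: list) -> None:
    """Sense-agnostic reads fully contained in the normalizer segment."""
    lo, hi = segment
    lens = rng.choice(cfg.lengths, size=n, p=cfg.length_probs)
    orients = rng.integers(0, 2, size=n)
    for i, (ln, o) in enumerate(zip(lens, orients)):
        ln = int(ln)
        start = int(rng.integers(lo, hi - ln + 1))
        template = seq[start:start + ln]
        rid = f"{prefix}_normalizer_{i:06d}"
        if o:
            records.append(SmallRNARead(rid, revcomp(template)))
            rows.append((rid, source_id, "normalizer", start + ln - 1, ln, ANTISENSE))
        else:
            records.append(SmallRNARead(rid, template))
            rows.append((rid, source_id, "normalizer", start, ln, SENSE))


def _emit_filler(rng: np.random.Generator, n: int, cfg: SimConfig,
                 prefix: str, records: list, rows: list) -> None:
    """Library filler: random sequences matching nothing in the references."""
    if n <= 0:
        return
    lens = rng.choice(cfg.lengths, size=n, p=cfg.length_probs)
    chars = rng.integers(0, 4, size=(n, _MAX_READ_LEN))
    base_lookup = np.array(list("ACGT"))
    for i in range(n):
        ln = int(lens[i])
        rid = f"{prefix}_filler_{i:06d}"
        records.append(SmallRNARead(rid, "".join(base_lookup[chars[i, :ln]])))
        rows.append((rid, "", "filler", -1, ln, SENSE))


def _provenance(rows: list) -> pd.DataFrame:
    return pd.DataFrame(
        rows, columns=["read_id", "source_id", "region", "position",
                       "length", "orientation"])


# ---------------------------------------------------------------------------
# Sensor scenario

def simulate_sensor_scenario(cfg: SimConfig, genotype: GenotypeSpec | str,
                             construct: TransgeneConstruct | None = None,
                             ) -> tuple[ReadSet, TruthTable]:
    """Simulate one small-RNA library from a sensor-bearing animal.

    Proximal (secondary) antisense reads fall within ``proximal_window`` nt
    of the target-site segment when the genotype's secondary tier is
    active; distal (tertiary) reads cover the remainder of the construct
    only when the tertiary tier is also active; a uniform antisense
    background and his-58 normalizer reads are always emitted, and random
    filler reads pad the library to the configured depth.
    """
    g = GENOTYPES[genotype] if isinstance(genotype, str) else genotype
    if construct is None:
        construct = make_sensor_construct()
    if construct.target_site_interval is None:
        raise SimulationError(f"{construct.id}: construct has no target site")

    seq = construct.sequence
    L = construct.length
    s, e = construct.target_site_interval
    prox_lo = max(0, s - cfg.proximal_window)
    prox_hi = min(L, e + cfg.proximal_window)
    proximal_iv = [(prox_lo, prox_hi)]
    distal_iv = [iv for iv in [(0, prox_lo), (prox_hi, L)] if iv[0] < iv[1]]
    distal_len = sum(b - a for a, b in distal_iv)

    exp_prox = cfg.lambda_proximal * (prox_hi - prox_lo) * cfg.depth \
        if g.secondary_active else 0.0
    exp_dist = cfg.lambda_distal * distal_len * cfg.depth \
        if g.tertiary_active else 0.0
    exp_bg = cfg.lambda_background * L * cfg.depth

    rng = np.random.default_rng(cfg.seed)
    records: list[SmallRNARead] = []
    rows: list = []
    prefix = f"{g.name.replace(';', '_')}"
    n_prox = int(rng.poisson(exp_prox))
    n_dist = int(rng.poisson(exp_dist))
    n_bg = int(rng.poisson(exp_bg))
    n_his = int(rng.poisson(cfg.his58_rate))
    if n_prox:
        _emit_antisense(rng, seq, proximal_iv, n_prox, cfg, construct.id,
                        "proximal", prefix, records, rows)
    if n_dist:
        _emit_antisense(rng, seq, distal_iv, n_dist, cfg, construct.id,
                        "distal", prefix, records, rows)
    if n_bg:
        _emit_antisense(rng, seq, [(0, L)], n_bg, cfg, construct.id,
                        "background", prefix, records, rows)
    if n_his:
        _emit_normalizer(rng, seq, construct.segment_interval("his-58"),
                         n_his, cfg, construct.id, prefix, records, rows)
    _emit_filler(rng, cfg.depth - len(records), cfg, prefix, records, rows)

    truth = TruthTable(
        transcripts=pd.DataFrame([{
            "transcript_id": construct.id,
            "class_label": "targeted",
            "site_start": s, "site_end": e,
            "expected_proximal": exp_prox,
            "expected_distal": exp_dist,
            "expected_background": exp_bg,
        }]),
        genotype=g.name, config=cfg)
    return ReadSet(records, provenance=_provenance(rows)), truth


# ---------------------------------------------------------------------------
# Operon scenarios (trans-silencing / RNAi feeding)

def simulate_operon_scenario(cfg: SimConfig, scenario: str,
                             ) -> tuple[ReadSet, TruthTable]:
    """Operon-reporter read sets for trans-silencing and feeding scenarios.

    ``trans_silenced``: tertiary-type antisense reads across the whole
    operon (mCherry and GFP) at the distal rate.  ``outcrossed``: the same
    but with the GFP portion reduced to 30% of the mCherry rate.
    ``rnai_feeding_P0``: dsRNA-trigger reads concentrated on GFP at the
    proximal rate; ``rnai_feeding_F2``: inherited reads across the operon
    at the distal rate.
    """
    construct = make_operon_construct()
    seq, L = construct.sequence, construct.length
    gfp = construct.segment_interval("gfp")
    mch = construct.segment_interval("mcherry")
    regions: list[tuple[list[tuple[int, int]], float, str]] = []
    if scenario == "trans_silenced":
        regions.append(([(0, L)], cfg.lambda_distal * L * cfg.depth, "distal"))
    elif scenario == "outcrossed":
        non_gfp = [(0, gfp[0]), (gfp[1], L)]
        nlen = sum(b - a for a, b in non_gfp)
        regions.append((non_gfp, cfg.lambda_distal * nlen * cfg.depth, "distal"))
        regions.append(([gfp], 0.3 * cfg.lambda_distal * (gfp[1] - gfp[0])
                        * cfg.depth, "distal_gfp"))
    elif scenario == "rnai_feeding_P0":
        regions.append(([gfp], cfg.lambda_proximal * (gfp[1] - gfp[0])
                        * cfg.depth, "proximal"))
    elif scenario == "rnai_feeding_F2":
        regions.append(([(0, L)], cfg.lambda_distal * L * cfg.depth, "distal"))
    else:
        raise SimulationError(f"unknown operon scenario {scenario!r}")

    rng = np.random.default_rng(cfg.seed)
    records: list[SmallRNARead] = []
    rows: list = []
    exp = {}
    for intervals, mean, tag in regions:
        n = int(rng.poisson(mean))
        exp[tag] = mean
        if n:
            _emit_antisense(rng, seq, intervals, n, cfg, construct.id, tag,
                            scenario, records, rows)
    n_bg = int(rng.poisson(cfg.lambda_background * L * cfg.depth))
    if n_bg:
        _emit_antisense(rng, seq, [(0, L)], n_bg, cfg, construct.id,
                        "background", scenario, records, rows)
    _emit_filler(rng, cfg.depth - len(records), cfg, scenario, records, rows)
    truth = TruthTable(
        transcripts=pd.DataFrame([{
            "transcript_id": construct.id, "class_label": scenario,
            "site_start": -1, "site_end": -1,
            **{f"expected_{k}": v for k, v in exp.items()},
        }]),
        genotype=scenario, config=cfg)
    return ReadSet(records, provenance=_provenance(rows)), truth


# ---------------------------------------------------------------------------
# Genome-like panel

# genotype-insensitive shape archetypes for the untargeted fraction of the
# panel; weights are relative read densities along the gene (by relative
# position x in [0,1)).  Several distinct shapes are emitted so the
# clustering sees the kind of pattern diversity real 22G targets show.
_FLAT_ARCHETYPES = ("uniform", "ramp_up", "ramp_down", "edges", "mid_block",
                    "double_peak")

# every archetype mixes a uniform baseline with a shape component: real
# 22G coverage on an expressed target is never exactly zero anywhere along
# the transcript, and the baseline keeps every bin populated
_ARCHETYPE_BASELINE = 0.15


def _archetype_weights(name: str, L: int) -> np.ndarray:
    x = (np.arange(L) + 0.5) / L
    if name == "uniform":
        shape = np.ones(L)
    elif name == "ramp_up":
        shape = 4.0 * x ** 3
    elif name == "ramp_down":
        shape = 4.0 * (1.0 - x) ** 3
    elif name == "edges":
        shape = ((x < 0.15) | (x >= 0.85)) / 0.30
    elif name == "mid_block":
        shape = ((x >= 0.35) & (x < 0.65)) / 0.30
    elif name == "double_peak":
        g = (np.exp(-0.5 * ((x - 0.30) / 0.05) ** 2)
             + np.exp(-0.5 * ((x - 0.70) / 0.05) ** 2))
        shape = g / g.mean()
    else:
        raise AssertionError(name)
    return _ARCHETYPE_BASELINE + (1.0 - _ARCHETYPE_BASELINE) * shape


def _emit_weighted(rng: np.random.Generator, seq: str, weights: np.ndarray,
                   n: int, cfg: SimConfig, source_id: str, region: str,
                   prefix: str, records: list, rows: list) -> None:
    cpos = _c_positions(seq)
    cpos = cpos[cpos >= _MAX_READ_LEN - 1]
    if cpos.size == 0:
        raise SimulationError(f"{source_id}: no template-C positions")
    w = weights[cpos]
    total = w.sum()
    if total <= 0:
        raise SimulationError(f"{source_id}: zero total weight for {region}")
    p5s = rng.choice(cpos, size=n, p=w / total)
    lens = rng.choice(cfg.lengths, size=n, p=cfg.length_probs)
    for i, (p5, ln) in enumerate(zip(p5s, lens)):
        p5, ln = int(p5), int(ln)
        rid = f"{prefix}_{region}_{i:06d}"
        records.append(SmallRNARead(rid, revcomp(seq[p5 - ln + 1:p5 + 1])))
        rows.append((rid, source_id, region, p5, ln, ANTISENSE))


@dataclass
class PanelData:
    references: list[TranscriptModel]
    pirnas: list[PiRNA]
    readsets: dict[str, ReadSet]
    truth: TruthTable


def simulate_genome_panel(cfg: SimConfig,
                          genotypes: Sequence[str] = ("wild_type", "nrde-4",
                                                      "prg-1"),
                          ) -> PanelData:
    """Simulate a panel of genes with genotype-dependent 22G patterns.

    ``cluster6_like`` genes (fraction_cluster6_like of the panel) carry a
    perfect-or-near piRNA site in the 3' half; in the wild type they show
    proximal reads around the site plus distal reads over the rest of the
    gene, in nuclear-RNAi mutants only the proximal reads remain (5'-bin
    loss), and in prg-1 all targeted reads vanish.  ``cluster1_like`` genes
    mirror this with 5' sites and 3' loss.  The remaining genes are
    genotype-insensitive, with one of several distinct 22G shape
    archetypes.  Per-gene expected totals are depth / n_genes.
    """
    if cfg.n_genes < 10:
        raise SimulationError("n_genes must be >= 10")
    rng = np.random.default_rng(cfg.seed)
    n6 = int(round(cfg.n_genes * cfg.fraction_cluster6_like))
    n1 = int(round(cfg.n_genes * cfg.fraction_cluster1_like))
    n_flat = cfg.n_genes - n6 - n1

    refs: list[TranscriptModel] = []
    pirnas: list[PiRNA] = []
    truth_rows: list[dict] = []
    gene_meta: list[dict] = []

    # untargeted genes are abundant piRNA-independent 22G targets; giving
    # them higher expression keeps library composition stable when the
    # targeted genes lose reads in mutants
    fold = cfg.untargeted_expression_fold
    unit = cfg.depth / ((n6 + n1) + fold * n_flat)
    per_gene_targeted = unit
    per_gene_flat = fold * unit

    labels = (["cluster6_like"] * n6 + ["cluster1_like"] * n1
              + [_FLAT_ARCHETYPES[i % len(_FLAT_ARCHETYPES)] + "_flat"
                 for i in range(n_flat)])
    for gi, label in enumerate(labels):
        gid = f"gene_{gi:04d}"
        L = int(rng.integers(1180, 1221))
        seq = _random_seq(rng, L)
        site_start = site_end = -1
        pid = ""
        if label in ("cluster6_like", "cluster1_like"):
            # site midpoint at a fixed relative position (3' or 5' half)
            # with small jitter; embedded antisense with 0-2 mismatches
            rel = 0.76 if label == "cluster6_like" else 0.24
            mid = int(rel * L) + int(rng.integers(-5, 6))
            site_start = mid - 10
            site_end = site_start + 21
            pid = f"21UR-sim-{gi:04d}"
            pir = PiRNA(pid, "T" + _random_seq(rng, 20))
            pirnas.append(pir)
            window = list(revcomp(pir.sequence))
            n_mut = int(rng.integers(0, 3))
            for pos in rng.choice(21, size=n_mut, replace=False):
                alt = [b for b in "ACGT" if b != window[pos]]
                window[pos] = alt[int(rng.integers(0, 3))]
            seq = seq[:site_start] + "".join(window) + seq[site_end:]
        refs.append(TranscriptModel.from_sequence(gid, seq))
        gene_meta.append({"gid": gid, "label": label, "L": L,
                          "site": (site_start, site_end), "seq_index": gi})
        truth_rows.append({"transcript_id": gid, "class_label": label,
                           "site_start": site_start, "site_end": site_end,
                           "pirna_id": pid})

    readsets: dict[str, ReadSet] = {}
    for gname in genotypes:
        g = GENOTYPES[gname]
        records: list[SmallRNARead] = []
        rows: list = []
        prefix = gname.replace(";", "_").replace("-", "")
        for meta in gene_meta:
            gid, label, L = meta["gid"], meta["label"], meta["L"]
            seq = refs[meta["seq_index"]].sequence
            gprefix = f"{prefix}_{gid}"
            if label.endswith("_flat"):
                arch = label[:-5]
                n = int(rng.poisson(per_gene_flat))
                if n:
                    _emit_weighted(rng, seq, _archetype_weights(arch, L),
                                   n, cfg, gid, "flat", gprefix, records,
                                   rows)
                exp_p = exp_d = 0.0
            else:
                s, e = meta["site"]
                lo = max(0, s - cfg.proximal_window)
                hi = min(L, e + cfg.proximal_window)
                distal_iv = [iv for iv in [(0, lo), (hi, L)] if iv[0] < iv[1]]
                exp_p = per_gene_targeted / 2 if g.secondary_active else 0.0
                exp_d = per_gene_targeted / 2 if g.tertiary_active else 0.0
                n_p = int(rng.poisson(exp_p))
                n_d = int(rng.poisson(exp_d))
                if n_p:
                    _emit_antisense(rng, seq, [(lo, hi)], n_p, cfg, gid,
                                    "proximal", gprefix, records, rows)
                if n_d:
                    _emit_antisense(rng, seq, distal_iv, n_d, cfg, gid,
                                    "distal", gprefix, records, rows)
            n_bg = int(rng.poisson(cfg.lambda_background * L * cfg.depth))
            if n_bg:
                _emit_antisense(rng, seq, [(0, L)], n_bg, cfg, gid,
                                "background", gprefix, records, rows)
            for col, val in ((f"expected_proximal_{gname}", exp_p),
                             (f"expected_distal_{gname}", exp_d)):
                truth_rows[meta["seq_index"]][col] = val
        readsets[gname] = ReadSet(records, provenance=_provenance(rows))

    truth = TruthTable(transcripts=pd.DataFrame(truth_rows), config=cfg)
    return PanelData(references=refs, pirnas=pirnas, readsets=readsets,
                     truth=truth)


# ---------------------------------------------------------------------------
# IP simulation

def simulate_ip_pair(cfg: SimConfig, base: ReadSet,
                     control: bool = False) -> tuple[ReadSet, ReadSet]:
    """Resample a base library as (input, IP) with Argonaute-bound enrichment.

    Construct-antisense reads (proximal/distal/background provenance) carry
    weight ``ip_fold`` in the IP resampling; all other reads weight 1.  A
    control IP (``control=True``, emulating the pulldown from a mutant
    lacking the Argonaute) uses weight 1 throughout.  The input set is the
    base itself.
    """
    if cfg.ip_fold < 1:
        raise SimulationError("ip_fold must be >= 1")
    if len(base) == 0:
        raise SimulationError("empty base read set")
    if base.provenance is None:
        raise SimulationError("base read set lacks provenance tags")
    rng = np.random.default_rng(cfg.seed + (1 if control else 2))
    prov = base.provenance
    antisense_construct = (
        prov["region"].isin(["proximal", "distal", "background"])
        & (prov["orientation"] == ANTISENSE)).to_numpy()
    if control:
        weights = np.ones(len(base.reads))
    else:
        weights = np.where(antisense_construct, cfg.ip_fold, 1.0)
    weights = weights / weights.sum()
    idx = rng.choice(len(base.reads), size=len(base.reads), p=weights)
    tag = "ctrl" if control else "ip"
    prov_rows = list(prov.itertuples(index=False, name=None))
    records = []
    rows = []
    for i, j in enumerate(idx):
        src = base.reads[j]
        rid = f"{tag}_{i:06d}"
        records.append(SmallRNARead(rid, src.sequence))
        _, source_id, region, position, length, orientation = prov_rows[j]
        rows.append((rid, source_id, region, position, length, orientation))
    return base, ReadSet(records, provenance=_provenance(rows))


# ---------------------------------------------------------------------------
# Fixture output

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture(outdir: str | Path, cfg: SimConfig,
                  references: Sequence[TranscriptModel] = (),
                  pirnas: Sequence[PiRNA] = (),
                  readsets: dict[str, ReadSet] | None = None,
                  truth: TruthTable | None = None) -> dict:
    """Write FASTA/FASTQ/TSV fixture files plus a JSON manifest.

    The manifest echoes the seed and full config and lists every file with
    its record count and sha256, so re-runs are byte-verifiable.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "config": cfg.to_dict(), "files": {}}

    def register(path: Path, n_records: int) -> None:
        manifest["files"][path.name] = {
            "records": n_records, "sha256": _sha256(path)}

    if references:
        p = outdir / "references.fasta"
        with open(p, "w") as fh:
            for t in references:
                fh.write(f">{t.id}\n{t.sequence}\n")
        register(p, len(references))
    if pirnas:
        p = outdir / "pirnas.fasta"
        with open(p, "w") as fh:
            for q in pirnas:
                fh.write(f">{q.id}\n{q.sequence}\n")
        register(p, len(pirnas))
    for name, rs in (readsets or {}).items():
        p = outdir / f"reads_{name.replace(';', '_')}.fastq"
        rs.write_fastq(p)
        register(p, len(rs))
        if rs.provenance is not None:
            pp = outdir / f"provenance_{name.replace(';', '_')}.tsv"
            rs.provenance.to_csv(pp, sep="\t", index=False)
            register(pp, len(rs.provenance))
    if truth is not None:
        p = outdir / "truth.tsv"
        truth.transcripts.to_csv(p, sep="\t", index=False)
        register(p, len(truth.transcripts))

    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# Scenario presets

def _sensor_preset(genotype: str):
    def run(cfg: SimConfig):
        return simulate_sensor_scenario(cfg, genotype)
    return run


def _operon_preset(scenario: str):
    def run(cfg: SimConfig):
        return simulate_operon_scenario(cfg, scenario)
    return run


SCENARIOS = {
    "sensor_wt": _sensor_preset("wild_type"),
    "sensor_prg1": _sensor_preset("prg-1"),
    "sensor_mut16": _sensor_preset("mut-16"),
    "sensor_hrde1": _sensor_preset("hrde-1"),
    "sensor_nrde": _sensor_preset("nrde-4"),
    "operon_trans_silenced": _operon_preset("trans_silenced"),
    "operon_outcrossed": _operon_preset("outcrossed"),
    "rnai_feeding_P0": _operon_preset("rnai_feeding_P0"),
    "rnai_feeding_F2": _operon_preset("rnai_feeding_F2"),
    "genome_panel": simulate_genome_panel,
}
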