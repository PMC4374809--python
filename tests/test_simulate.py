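"""Generator contracts: genotype logic, read provenance, determinism,
convergence of empirical rates, and fixture output."""

import json

import numpy as np
import pandas as pd
import pytest

from pirnaspread import simulate
from pirnaspread.reference import revcomp
from pirnaspread.simulate import (GENOTYPES, GenotypeSpec, SimConfig,
                                  SimulationError, simulate_genome_panel,
                                  simulate_ip_pair, simulate_operon_scenario,
                                  simulate_sensor_scenario, write_fixture)


class TestGenotypeSpec:
    def test_tertiary_requires_secondary(self):
        with pytest.raises(SimulationError):
            GenotypeSpec("bad", secondary_active=False, tertiary_active=True)

    def test_preset_epistasis(self):
        for g in GENOTYPES.values():
            assert not (g.tertiary_active and not g.secondary_active)
        assert GENOTYPES["wild_type"].tertiary_active
        assert not GENOTYPES["hrde-1"].tertiary_active
        assert GENOTYPES["hrde-1"].secondary_active
        assert not GENOTYPES["prg-1"].secondary_active


class TestSimConfig:
    def test_bad_probabilities_rejected(self):
        with pytest.raises(SimulationError):
            SimConfig(read_length_distribution=((21, 0.5), (22, 0.4)))

    def test_negative_rate_rejected(self):
        with pytest.raises(SimulationError):
            SimConfig(lambda_proximal=-1.0)

    def test_fractions_over_one_rejected(self):
        with pytest.raises(SimulationError):
            SimConfig(fraction_cluster6_like=0.8, fraction_cluster1_like=0.3)


class TestSensorScenario:
    def test_wild_type_has_proximal_and_distal(self, shallow_cfg):
        rs, truth = simulate_sensor_scenario(shallow_cfg, "wild_type")
        regions = rs.provenance.region.value_counts()
        assert regions.get("proximal", 0) > 0
        assert regions.get("distal", 0) > 0
        assert truth.transcripts.expected_distal.iloc[0] > 0

    def test_nuclear_rnai_mutant_lacks_distal(self, shallow_cfg):
        rs, truth = simulate_sensor_scenario(shallow_cfg, "hrde-1")
        regions = rs.provenance.region.value_counts()
        assert regions.get("proximal", 0) > 0
        assert regions.get("distal", 0) == 0
        assert truth.transcripts.expected_distal.iloc[0] == 0

    def test_pirna_pathway_null_without_background_is_silent(self):
        cfg = SimConfig(seed=5, depth=5000, lambda_background=0.0)
        rs, _ = simulate_sensor_scenario(cfg, "prg-1")
        regions = rs.provenance.region.value_counts()
        for region in ("proximal", "distal", "background"):
            assert regions.get(region, 0) == 0

    def test_reads_are_antisense_substrings(self, shallow_cfg, sensor_construct):
        rs, _ = simulate_sensor_scenario(shallow_cfg, "wild_type",
                                         sensor_construct)
        seq = sensor_construct.sequence
        prov = rs.provenance.set_index("read_id")
        for r in rs.reads:
            region = prov.loc[r.id, "region"]
            if region in ("proximal", "distal", "background"):
                assert revcomp(r.sequence) in seq
                assert r.first_nt == "G"

    def test_depth_padding_with_filler(self, shallow_cfg):
        rs, _ = simulate_sensor_scenario(shallow_cfg, "wild_type")
        assert len(rs) == shallow_cfg.depth

    def test_seed_repetition_byte_identical(self, tmp_path):
        cfg = SimConfig(seed=21, depth=3000)
        for d in ("a", "b"):
            rs, _ = simulate_sensor_scenario(cfg, "wild_type")
            rs.write_fastq(tmp_path / f"{d}.fastq")
        assert (tmp_path / "a.fastq").read_bytes() \
            == (tmp_path / "b.fastq").read_bytes()

    def test_empirical_rates_converge(self):
        # empirical region counts within 3 standard errors of Poisson mean
        cfg = SimConfig(seed=33, depth=100_000)
        rs, truth = simulate_sensor_scenario(cfg, "wild_type")
        regions = rs.provenance.region.value_counts()
        row = truth.transcripts.iloc[0]
        for region, expected in (("proximal", row.expected_proximal),
                                 ("distal", row.expected_distal)):
            got = regions.get(region, 0)
            assert abs(got - expected) <= 3 * np.sqrt(expected), region

    def test_degenerate_window_raises(self):
        from pirnaspread.reference import Segment, build_transgene
        construct = build_transgene("deg", [
            Segment("cds", "coding", "A" * 400),
            Segment("site", "target_site", "A" * 121, pirna_id="p"),
        ])
        with pytest.raises(SimulationError, match="template-C"):
            simulate_sensor_scenario(SimConfig(seed=1, depth=2000), "wild_type",
                                     construct)


class TestOperonScenarios:
    @pytest.mark.parametrize("scenario", ["trans_silenced", "outcrossed",
                                          "rnai_feeding_P0", "rnai_feeding_F2"])
    def test_scenarios_emit_antisense_reads(self, scenario):
        cfg = SimConfig(seed=2, depth=20_000)
        rs, truth = simulate_operon_scenario(cfg, scenario)
        prov = rs.provenance
        assert (prov.region != "filler").sum() > 0
        assert truth.genotype == scenario

    def test_outcrossed_gfp_reduction(self):
        cfg = SimConfig(seed=3, depth=50_000)
        rs, _ = simulate_operon_scenario(cfg, "outcrossed")
        construct = simulate.make_operon_construct()
        gfp = construct.segment_interval("gfp")
        prov = rs.provenance
        emitted = prov[prov.region.str.startswith("distal")]
        gfp_hits = emitted[(emitted.position >= gfp[0])
                           & (emitted.position < gfp[1])]
        non_gfp = emitted.drop(gfp_hits.index)
        gfp_len = gfp[1] - gfp[0]
        density_ratio = (len(gfp_hits) / gfp_len) \
            / (len(non_gfp) / (construct.length - gfp_len))
        assert density_ratio < 0.6

    def test_unknown_scenario_rejected(self):
        with pytest.raises(SimulationError, match="unknown"):
            simulate_operon_scenario(SimConfig(), "bogus")


class TestGenomePanel:
    @pytest.fixture(scope="class")
    def panel(self):
        cfg = SimConfig(seed=12, depth=60_000, n_genes=60)
        return simulate_genome_panel(cfg)

    def test_class_bookkeeping(self, panel):
        labels = panel.truth.transcripts.class_label
        assert (labels == "cluster6_like").sum() == 30
        assert (labels == "cluster1_like").sum() == 12

    def test_sites_in_expected_halves(self, panel):
        truth = panel.truth.transcripts
        refs = {t.id: t for t in panel.references}
        for row in truth.itertuples(index=False):
            if row.class_label == "cluster6_like":
                L = refs[row.transcript_id].spliced_length
                assert row.site_start >= L // 2
            elif row.class_label == "cluster1_like":
                L = refs[row.transcript_id].spliced_length
                assert row.site_end <= L // 2

    def test_embedded_sites_within_three_mismatches(self, panel):
        pirnas = {p.id: p for p in panel.pirnas}
        refs = {t.id: t for t in panel.references}
        truth = panel.truth.transcripts
        targeted = truth[truth.pirna_id != ""]
        for row in targeted.itertuples(index=False):
            window = refs[row.transcript_id].sequence[
                row.site_start:row.site_end]
            target = revcomp(pirnas[row.pirna_id].sequence)
            mm = sum(a != b for a, b in zip(window, target))
            assert mm <= 3

    def test_nrde_loses_five_prime_reads_of_cluster6(self, panel):
        truth = panel.truth.transcripts.set_index("transcript_id")
        refs = {t.id: t for t in panel.references}
        prov = panel.readsets["nrde-4"].provenance
        for gid in truth[truth.class_label == "cluster6_like"].index[:10]:
            L = refs[gid].spliced_length
            positions = prov[prov.source_id == gid].position
            five = (positions < L // 2).sum()
            three = (positions >= L // 2).sum()
            assert three > five

    def test_prg1_removes_targeted_reads(self, panel):
        truth = panel.truth.transcripts.set_index("transcript_id")
        prov = panel.readsets["prg-1"].provenance
        targeted = truth[truth.class_label.isin(
            ["cluster6_like", "cluster1_like"])].index
        emitted = prov[prov.region.isin(["proximal", "distal"])]
        assert not emitted.source_id.isin(set(targeted)).any()

    def test_tertiary_only_with_secondary(self, panel):
        for gname, rs in panel.readsets.items():
            g = GENOTYPES[gname]
            regions = set(rs.provenance.region)
            if "distal" in regions:
                assert "proximal" in regions

    def test_reads_never_span_introns(self, panel):
        # panel transcripts are emitted spliced; every read is an exact
        # reverse-complement substring of its spliced source
        refs = {t.id: t for t in panel.references}
        rs = panel.readsets["wild_type"]
        prov = rs.provenance.set_index("read_id")
        sample = rs.reads[:500]
        for r in sample:
            src = prov.loc[r.id, "source_id"]
            assert revcomp(r.sequence) in refs[src].sequence

    def test_fraction_sum_over_one_rejected(self):
        with pytest.raises(SimulationError):
            simulate_genome_panel(SimConfig(
                fraction_cluster6_like=0.7, fraction_cluster1_like=0.4))

    def test_too_few_genes_rejected(self):
        with pytest.raises(SimulationError, match="n_genes"):
            simulate_genome_panel(SimConfig(n_genes=5))


class TestIPPair:
    def test_fold_one_indistinguishable(self):
        from scipy.stats import chi2_contingency
        cfg = SimConfig(seed=6, depth=100_000, ip_fold=1.0)
        base, _ = simulate_sensor_scenario(cfg, "wild_type")
        _, ip = simulate_ip_pair(cfg, base, control=False)
        _, ctrl = simulate_ip_pair(cfg, base, control=True)
        counts = pd.DataFrame({
            "ip": ip.provenance.region.value_counts(),
            "ctrl": ctrl.provenance.region.value_counts()}).fillna(0)
        _, p, _, _ = chi2_contingency(counts.T.to_numpy())
        assert p > 0.01

    def test_fold_below_one_rejected(self):
        cfg = SimConfig(ip_fold=0.5)
        base, _ = simulate_sensor_scenario(SimConfig(seed=1, depth=1000),
                                           "wild_type")
        with pytest.raises(SimulationError, match="ip_fold"):
            simulate_ip_pair(cfg, base)

    def test_empty_base_rejected(self):
        from pirnaspread.reads import ReadSet
        with pytest.raises(SimulationError, match="empty"):
            simulate_ip_pair(SimConfig(), ReadSet([]))

    def test_enrichment_shifts_composition(self):
        cfg = SimConfig(seed=7, depth=50_000, ip_fold=10.0)
        base, _ = simulate_sensor_scenario(cfg, "wild_type")
        _, ip = simulate_ip_pair(cfg, base, control=False)
        frac = lambda rs: rs.provenance.region.isin(
            ["proximal", "distal", "background"]).mean()
        assert frac(ip) > 3 * frac(base)


class TestWriteFixture:
    def test_manifest_counts_and_determinism(self, tmp_path):
        cfg = SimConfig(seed=9, depth=2000)
        rs, truth = simulate_sensor_scenario(cfg, "wild_type")
        m1 = write_fixture(tmp_path / "a", cfg, readsets={"wt": rs},
                           truth=truth)
        assert m1["files"]["reads_wt.fastq"]["records"] == len(rs)
        assert m1["seed"] == 9
        rs2, truth2 = simulate_sensor_scenario(cfg, "wild_type")
        m2 = write_fixture(tmp_path / "b", cfg, readsets={"wt": rs2},
                           truth=truth2)
        assert m1["files"]["reads_wt.fastq"]["sha256"] \
            == m2["files"]["reads_wt.fastq"]["sha256"]
        manifest_on_disk = json.loads(
            (tmp_path / "a" / "manifest.json").read_text())
        assert manifest_on_disk["config"]["depth"] == 2000

    def test_unwritable_destination_raises(self, tmp_path):
        # a path whose parent is a regular file can never be created
        blocker = tmp_path / "blocker"
        blocker.write_text("")
        cfg = SimConfig(seed=1, depth=100)
        rs, truth = simulate_sensor_scenario(cfg, "wild_type")
        with pytest.raises(OSError):
            write_fixture(blocker / "sub", cfg, readsets={"wt": rs},
                          truth=truth)
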