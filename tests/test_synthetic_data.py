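"""Synthetic-data generator: determinism, planted structure, count model."""

import numpy as np
import pytest

from ltr_cisnet.genome_context import classify_position, STREAM, IN, PART
from ltr_cisnet.ltr_detection import compute_ltr_identity
from ltr_cisnet.synthetic_data import (TruthEffect, generate_gene_annotation,
                                       generate_genome, plant_element,
                                       simulate_counts, simulate_study)


class TestGenerateGenome:
    def test_deterministic_for_fixed_seed(self):
        a = generate_genome(1, 50_000, 0.4, seed=7)
        b = generate_genome(1, 50_000, 0.4, seed=7)
        assert a == b
        c = generate_genome(1, 50_000, 0.4, seed=8)
        assert a != c

    def test_zero_scaffolds_gives_empty_genome(self):
        assert generate_genome(0, [], 0.4, seed=1) == {}

    def test_gc_fraction_within_002(self):
        g = generate_genome(2, [30_000, 30_000], 0.4, seed=11)
        seq = "".join(g.values())
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.4) < 0.02

    @pytest.mark.parametrize("kwargs", [
        dict(n_scaffolds=1, scaffold_lengths=[0], gc=0.4),
        dict(n_scaffolds=1, scaffold_lengths=[500], gc=0.4),
        dict(n_scaffolds=1, scaffold_lengths=[5000], gc=0.0),
        dict(n_scaffolds=2, scaffold_lengths=[5000], gc=0.4),
    ])
    def test_invalid_inputs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            generate_genome(seed=1, **kwargs)


class TestPlantElement:
    def test_substitution_count_matches_requested_identity(self):
        g = generate_genome(1, 20_000, 0.4, seed=1)
        g, t = plant_element(g, "scf_1", 5000, ltr_len=300, internal_len=5000,
                             identity=0.85, tsd_len=4, domains=("pol",), seed=2)
        assert t.length == 5600
        seq = g["scf_1"]
        ltr5 = seq[t.ltr5_start:t.ltr5_end]
        ltr3 = seq[t.ltr3_start:t.ltr3_end]
        mism = sum(a != b for a, b in zip(ltr5, ltr3))
        assert mism == 45        # round((1 - 0.85) * 300)
        assert t.planted_identity == pytest.approx((300 - 45) / 300)

    def test_reextracted_identity_equals_planted(self, planted_genome):
        g, t = planted_genome
        seq = g["scf_1"]
        ident = compute_ltr_identity(seq[t.ltr5_start:t.ltr5_end],
                                     seq[t.ltr3_start:t.ltr3_end])
        assert ident == pytest.approx(t.planted_identity)

    def test_identity_one_gives_byte_identical_copies(self):
        g = generate_genome(1, 10_000, 0.4, seed=3)
        g, t = plant_element(g, "scf_1", 2000, ltr_len=200, internal_len=1500,
                             identity=1.0, seed=4)
        seq = g["scf_1"]
        assert seq[t.ltr5_start:t.ltr5_end] == seq[t.ltr3_start:t.ltr3_end]

    def test_tsd_flanks_identical(self, planted_genome):
        g, t = planted_genome
        seq = g["scf_1"]
        tsd_len = len(t.tsd_seq)
        assert seq[t.start - tsd_len:t.start] == t.tsd_seq
        assert seq[t.end:t.end + tsd_len] == t.tsd_seq

    def test_overrun_and_overlap_rejected(self):
        g = generate_genome(1, 10_000, 0.4, seed=5)
        with pytest.raises(ValueError, match="overruns"):
            plant_element(g, "scf_1", 8000, ltr_len=300, internal_len=5000)
        g2, t = plant_element(g, "scf_1", 2000, ltr_len=200, internal_len=1500)
        with pytest.raises(ValueError, match="overlaps"):
            plant_element(g2, "scf_1", 2500, ltr_len=200, internal_len=1500,
                          existing=[t])

    def test_bad_parameters_rejected(self):
        g = generate_genome(1, 10_000, 0.4, seed=6)
        with pytest.raises(ValueError):
            plant_element(g, "scf_1", 2000, ltr_len=50, internal_len=1000)
        with pytest.raises(ValueError):
            plant_element(g, "scf_1", 2000, ltr_len=200, internal_len=1000,
                          tsd_len=8)
        with pytest.raises(ValueError):
            plant_element(g, "scf_1", 2000, ltr_len=200, internal_len=1000,
                          domains=("nonsense",))


@pytest.fixture(scope="module")
def setting():
    g = generate_genome(1, 200_000, 0.35, seed=9)
    truths = []
    g, t1 = plant_element(g, "scf_1", 30_000, ltr_len=300,
                          internal_len=4000, seed=10, existing=truths)
    truths.append(t1)
    g, t2 = plant_element(g, "scf_1", 60_000, ltr_len=300,
                          internal_len=4000, seed=11, existing=truths)
    truths.append(t2)
    return g, truths


class TestGeneAnnotation:

    def test_requested_placements_are_realized(self, setting):
        g, truths = setting
        spec = [
            {"kind": "exon_in", "element": 0},
            {"kind": "exon_straddle", "element": 1},
            {"kind": "distance", "element": 1, "distance": 99_000, "side": "right"},
        ]
        genes, placements = generate_gene_annotation(g, truths, 5, spec, seed=12)
        assert len(genes) == 5
        assert len({gn.gene_id for gn in genes}) == 5
        for gene in genes:
            starts = [e.start for e in gene.exons]
            assert starts == sorted(starts)

        cls0 = classify_position(truths[0], genes)
        assert IN in cls0.classes
        cls1 = classify_position(truths[1], genes)
        assert PART in cls1.classes
        # the distance gene's nearest exon gap is exactly as requested
        far = next(gn for gn in genes if gn.gene_id == "gene_0003")
        gap = min(e.start for e in far.exons) - truths[1].end
        assert gap == 99_000

    def test_gene_free_scaffold_stays_stream(self):
        g = generate_genome(2, [50_000, 50_000], 0.35, seed=13)
        g, t = plant_element(g, "scf_1", 10_000, ltr_len=200, internal_len=2000)
        genes, _ = generate_gene_annotation(
            g, [t], 3, [{"kind": "free", "scaffold": "scf_2"}] * 3, seed=14)
        cls = classify_position(t, genes)
        assert cls.classes == {STREAM}
        assert cls.no_gene_scaffold

    def test_unsatisfiable_placement_rejected(self, setting):
        g, truths = setting
        with pytest.raises(ValueError):
            generate_gene_annotation(
                g, truths, 1,
                [{"kind": "distance", "element": 0, "distance": 10**7}], seed=15)
        with pytest.raises(ValueError, match="more placement"):
            generate_gene_annotation(g, truths, 0, [{"kind": "free"}], seed=16)


class TestSimulateCounts:
    CK = ("CK1", "CK2")
    NPV = ("NPV1", "NPV2")

    def test_planted_effect_recovered_in_group_ratio(self):
        lens = {f"f{i}": 1000 for i in range(300)}
        effects = [TruthEffect(f, 3.0, 0.05, 500.0) for f in lens]
        counts = simulate_counts(lens, self.CK, self.NPV, effects, 2e7, seed=21)
        ck = counts[list(self.CK)].mean(axis=1)
        npv = counts[list(self.NPV)].mean(axis=1)
        lfc = np.log2(npv / ck)
        assert abs(lfc.mean() - 3.0) < 0.05

    def test_null_effect_gives_flat_ratio(self):
        lens = {f"f{i}": 1000 for i in range(300)}
        counts = simulate_counts(lens, self.CK, self.NPV, (), 2e7, seed=22)
        lfc = np.log2(counts[list(self.NPV)].mean(axis=1)
                      / counts[list(self.CK)].mean(axis=1))
        assert abs(lfc.mean()) < 0.05

    def test_deterministic_and_validated(self):
        lens = {"a": 1000, "b": 2000}
        c1 = simulate_counts(lens, self.CK, self.NPV, (), 1e6, seed=5)
        c2 = simulate_counts(lens, self.CK, self.NPV, (), 1e6, seed=5)
        assert c1.equals(c2)
        with pytest.raises(ValueError):
            simulate_counts(lens, self.CK, self.NPV, (), 0.0, seed=5)
        with pytest.raises(ValueError, match="unknown feature"):
            simulate_counts(lens, self.CK, self.NPV,
                            [TruthEffect("zzz", 1.0)], 1e6, seed=5)
        with pytest.raises(ValueError):
            TruthEffect("a", 1.0, dispersion=0.0)


def test_simulate_study_is_deterministic():
    a = simulate_study(seed=3)
    b = simulate_study(seed=3)
    assert a.genome == b.genome
    assert a.counts.equals(b.counts)
    assert [t.id for t in a.truth_elements] == [t.id for t in b.truth_elements]
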