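"""Synthetic-data generators: composition, determinism, planted ground truth."""

import numpy as np
import pytest
from scipy import stats

from xylemtrn.errors import PlantingError, ValidationError
from xylemtrn.motifs import scan
from xylemtrn.simulate import (
    ExpressionDesign,
    PlantedElement,
    SyntheticTruth,
    full_trajectory_plan,
    generate_catalog,
    generate_expression,
    generate_promoters,
    generate_proteome,
    generate_reference_dataset,
)


class TestGenerateCatalog:
    def test_requested_composition(self):
        catalog = generate_catalog({"WND": 8, "TF": 108, "CW": 98, "PCD": 47}, seed=0)
        assert len(catalog) == 261
        assert len(catalog.with_role("WND")) == 8
        assert len(catalog.with_role("CW_secondary")) == 98
        assert len(catalog.with_role("PCD")) == 47

    def test_empty_and_negative(self):
        assert len(generate_catalog({"TF": 0, "PCD": 0}, seed=0)) == 0
        with pytest.raises(ValidationError):
            generate_catalog({"TF": -1}, seed=0)

    def test_deterministic(self, tmp_path):
        a = generate_catalog({"WND": 3, "TF": 20, "background": 10}, seed=42,
                             tf_families={"NAC": 5, "MYB": 5})
        b = generate_catalog({"WND": 3, "TF": 20, "background": 10}, seed=42,
                             tf_families={"NAC": 5, "MYB": 5})
        (tmp_path / "a.tsv").touch()
        a.to_tsv(tmp_path / "a.tsv")
        b.to_tsv(tmp_path / "b.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_family_split_and_tags(self):
        catalog = generate_catalog(
            {"TF": 10}, seed=0, tf_families={"NAC": 3, "MYB": 2},
            ortholog_tags={"NAC072_class": 2, "NAC045_class": 1},
        )
        families = [e.family for e in catalog]
        assert families == ["NAC"] * 3 + ["MYB"] * 2 + ["other"] * 5
        tagged = [sorted(e.ortholog_tags) for e in catalog]
        assert tagged[:3] == [["NAC072_class"], ["NAC072_class"], ["NAC045_class"]]


class TestGeneratePromoters:
    def test_planted_variant_written_at_offset(self, motifs):
        catalog = generate_catalog({"TF": 1}, seed=0)
        plan = [PlantedElement("TF0001", "SMRE", 150, "+", variant="ACCTAAT")]
        promoters, truth = generate_promoters(catalog, motifs, plan, window=400, seed=1)
        assert promoters["TF0001"][150:157] == "ACCTAAT"
        el = truth.planted_elements[0]
        assert (el.gene_id, el.motif_name, el.offset, el.strand) == ("TF0001", "SMRE", 150, "+")

    def test_minus_strand_written_as_reverse_complement(self, motifs):
        catalog = generate_catalog({"TF": 1}, seed=0)
        plan = [PlantedElement("TF0001", "SMRE", 10, "-", variant="ACCTAAT")]
        promoters, _ = generate_promoters(catalog, motifs, plan, window=100, seed=1)
        assert promoters["TF0001"][10:17] == "ATTAGGT"
        hits = scan(promoters["TF0001"], motifs["SMRE"], strands="minus")
        assert any(h.start == 10 for h in hits)

    def test_window_and_no_plantings(self, motifs):
        catalog = generate_catalog({"TF": 3}, seed=0)
        promoters, truth = generate_promoters(catalog, motifs, [], window=2000, seed=0)
        assert all(len(seq) == 2000 for seq in promoters.values())
        assert truth.planted_elements == []

    def test_offset_overflow_names_gene(self, motifs):
        catalog = generate_catalog({"TF": 1}, seed=0)
        plan = [PlantedElement("TF0001", "SMRE", 1998, "+")]
        with pytest.raises(PlantingError, match="TF0001"):
            generate_promoters(catalog, motifs, plan, window=2000, seed=0)

    def test_overlapping_plantings_rejected(self, motifs):
        catalog = generate_catalog({"TF": 1}, seed=0)
        plan = [
            PlantedElement("TF0001", "SMRE", 100, "+"),
            PlantedElement("TF0001", "WBOX", 103, "+"),
        ]
        with pytest.raises(PlantingError, match="overlap"):
            generate_promoters(catalog, motifs, plan, window=2000, seed=0)

    def test_deterministic(self, motifs):
        catalog = generate_catalog({"TF": 5}, seed=0)
        plan = [PlantedElement("TF0002", "TGTG", 50, "+")]
        a, _ = generate_promoters(catalog, motifs, plan, window=500, seed=9)
        b, _ = generate_promoters(catalog, motifs, plan, window=500, seed=9)
        assert a == b


class TestGenerateExpression:
    def _catalog(self, n=4):
        return generate_catalog({"TF": n}, seed=0)

    def test_zero_noise_recovers_planted_means(self):
        catalog = self._catalog()
        design = ExpressionDesign(base_level=16.0, effect_size=2.0, noise_sd=0.0)
        plan = full_trajectory_plan(catalog, {"TF0001": "I", "TF0002": "III"})
        matrix, _ = generate_expression(catalog, design, plan, seed=0)
        # group I at log2 means (4, 6, 8) -> 16, 64, 256
        assert matrix.loc["TF0001"].tolist() == [16, 16, 16, 64, 64, 64, 256, 256, 256]
        assert matrix.loc["TF0002"].tolist() == [16, 16, 16, 4, 4, 4, 1, 1, 1]
        # flat genes stay at base level: expected log2FC 0 at both comparisons
        assert matrix.loc["TF0003"].nunique() == 1

    def test_group_I_month2_exceeds_month1(self):
        """Planted upward step dominates replicate noise across many seeds.

        With effect 2 and noise 0.2 the month-2 minus month-1 sample-mean
        difference is N(2, 0.2^2 * 2/3); the normal tail gives a failure
        probability of ~7e-35, so every seed must recover the direction.
        """
        catalog = self._catalog(1)
        design = ExpressionDesign(effect_size=2.0, noise_sd=0.2)
        plan = {"TF0001": "I"}
        fail_p = stats.norm.cdf(0, loc=2.0, scale=0.2 * np.sqrt(2 / 3))
        assert fail_p < 1e-30
        for seed in range(300):
            matrix, _ = generate_expression(catalog, design, plan, seed=seed)
            row = np.log2(matrix.loc["TF0001"].to_numpy())
            assert row[3:6].mean() > row[0:3].mean()

    def test_low_effect_warns(self):
        catalog = self._catalog(1)
        design = ExpressionDesign(effect_size=0.3, noise_sd=0.3)
        with pytest.warns(UserWarning, match="effect_size"):
            generate_expression(catalog, design, {"TF0001": "I"}, seed=0)

    def test_plan_must_cover_catalog(self):
        catalog = self._catalog(2)
        with pytest.raises(ValidationError, match="missing gene"):
            generate_expression(catalog, ExpressionDesign(), {"TF0001": "I"}, seed=0)


class TestGenerateProteome:
    def _setup(self):
        catalog = generate_catalog({"TF": 3}, seed=0)
        design = ExpressionDesign(effect_size=2.0, noise_sd=0.0)
        plan = full_trajectory_plan(catalog, {"TF0001": "I", "TF0002": "I"})
        matrix, truth = generate_expression(catalog, design, plan, seed=0)
        return catalog, design, matrix, truth

    def test_consistent_and_discordant_by_construction(self):
        catalog, design, _, truth = self._setup()
        plan = {"P1": ("TF0001", "consistent"), "P2": ("TF0002", "discordant")}
        proteome, prot_truth = generate_proteome(catalog, truth, plan, design, seed=0)
        p1 = np.log2(proteome.loc["P1"].to_numpy())
        p2 = np.log2(proteome.loc["P2"].to_numpy())
        # consistent protein rises at both comparisons like its group-I transcript
        assert p1[3:6].mean() > p1[0:3].mean() and p1[6:9].mean() > p1[0:3].mean()
        # discordant protein is sign-flipped at one or both comparisons
        assert p2[3:6].mean() < p2[0:3].mean()
        assert prot_truth.planted_concordance == {"P1": "consistent", "P2": "discordant"}

    def test_unknown_gene_rejected(self):
        catalog, design, _, truth = self._setup()
        with pytest.raises(ValidationError, match="unknown gene"):
            generate_proteome(catalog, truth, {"P1": ("nope", "consistent")}, design, seed=0)

    def test_empty_plan_and_determinism(self):
        catalog, design, _, truth = self._setup()
        empty, _ = generate_proteome(catalog, truth, {}, design, seed=0)
        assert empty.empty
        plan = {"P1": ("TF0001", "consistent")}
        a, _ = generate_proteome(catalog, truth, plan, design, seed=5)
        b, _ = generate_proteome(catalog, truth, plan, design, seed=5)
        assert a.equals(b)


class TestTruthSerialization:
    def test_json_round_trip(self):
        truth = SyntheticTruth(
            seed=3,
            planted_elements=[PlantedElement("g1", "SMRE", 150, "+", "ACCTAAT")],
            planted_trajectory={"g1": "I", "g2": "flat"},
            planted_concordance={"P_g1": "discordant"},
        )
        assert SyntheticTruth.from_json(truth.to_json()) == truth

    def test_file_round_trip(self, tmp_path):
        truth = SyntheticTruth(seed=1, planted_trajectory={"g": "IV"})
        path = tmp_path / "truth.json"
        truth.to_json(path)
        assert SyntheticTruth.from_json(path) == truth


def test_reference_dataset_is_deterministic_and_complete():
    a = generate_reference_dataset(seed=2, n_background=20)
    b = generate_reference_dataset(seed=2, n_background=20)
    assert a.promoters == b.promoters
    assert a.expression.equals(b.expression)
    assert a.proteome.equals(b.proteome)
    assert len(a.catalog.with_role("WND")) == 8
    assert len(a.catalog.with_role("CW_secondary", "CW_primary")) == 98
    assert len(a.catalog.with_role("PCD")) == 47
    labels = list(a.truth.planted_concordance.values())
    assert labels.count("consistent") == 121 and labels.count("discordant") == 72
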