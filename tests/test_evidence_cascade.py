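import numpy as np
import pandas as pd
import pytest

from conftest import make_selected
from oracles import brute_force_pairs, brute_force_prioritized
from gliprio.evidence_cascade import (
    EvidenceTables,
    find_dnam_near_variants,
    further_prioritize,
    loci_from_tsv,
    loci_to_tsv,
    prioritize,
    run_cascade,
)
from gliprio.synthetic_data import (
    ScenarioTruth,
    default_truth,
    generate_evidence_tables,
)


def dme_frame(rows):
    """rows: (cpg_id, chrom, pos, context, significant)."""
    return pd.DataFrame(
        [
            {
                "cpg_id": c,
                "chrom": ch,
                "pos": p,
                "context": ctx,
                "effect_direction": "+",
                "p": 1e-8,
                "significant": sig,
            }
            for c, ch, p, ctx, sig in rows
        ]
    )


def eqtl_frame(rows):
    """rows: (variant_id, gene_id, tissue, significant)."""
    return pd.DataFrame(
        [
            {"variant_id": v, "gene_id": g, "tissue": t, "slope": 0.1, "p": 1e-9,
             "significant": s}
            for v, g, t, s in rows
        ]
    )


def eqtm_frame(rows):
    return pd.DataFrame(
        [{"cpg_id": c, "gene_id": g, "p": 1e-7, "significant": s} for c, g, s in rows]
    )


def dexpr_frame(rows):
    return pd.DataFrame(
        [
            {"gene_id": g, "exposure": e, "direction": "up", "p": 1e-6, "significant": s}
            for g, e, s in rows
        ]
    )


class TestFindDnamNearVariants:
    def test_exposure_context_within_flank_pairs(self):
        sel = make_selected([("rs1", "chr1", 1_000_000, "HDL", "current smoking", "AA")])
        dme = dme_frame([("cg1", "chr1", 1_400_000, "current smoking", True)])
        pairs = find_dnam_near_variants(sel, dme)
        assert len(pairs) == 1
        assert pairs.iloc[0]["distance"] == 400_000

    def test_context_mismatch_not_paired(self):
        sel = make_selected([("rs1", "chr1", 1_000_000, "HDL", "current smoking", "AA")])
        dme = dme_frame([("cg1", "chr1", 1_100_000, "SBP", True)])
        assert find_dnam_near_variants(sel, dme).empty

    def test_trait_context_also_pairs(self):
        sel = make_selected([("rs1", "chr1", 1_000_000, "HDL", "current smoking", "AA")])
        dme = dme_frame([("cg1", "chr1", 1_100_000, "HDL", True)])
        assert len(find_dnam_near_variants(sel, dme)) == 1

    def test_flank_boundary_inclusive_then_exclusive(self):
        sel = make_selected([("rs1", "chr1", 1_000_000, "HDL", "current smoking", "AA")])
        at = dme_frame([("cg1", "chr1", 1_500_000, "current smoking", True)])
        beyond = dme_frame([("cg1", "chr1", 1_500_001, "current smoking", True)])
        assert len(find_dnam_near_variants(sel, at)) == 1
        assert find_dnam_near_variants(sel, beyond).empty

    def test_insignificant_cpg_ignored(self):
        sel = make_selected([("rs1", "chr1", 1_000_000, "HDL", "current smoking", "AA")])
        dme = dme_frame([("cg1", "chr1", 1_100_000, "current smoking", False)])
        assert find_dnam_near_variants(sel, dme).empty

    def test_and_mode_requires_both_contexts(self):
        sel = make_selected([("rs1", "chr1", 1_000_000, "HDL", "current smoking", "AA")])
        dme_one = dme_frame([("cg1", "chr1", 1_100_000, "current smoking", True)])
        dme_both = dme_frame(
            [
                ("cg1", "chr1", 1_100_000, "current smoking", True),
                ("cg1", "chr1", 1_100_000, "HDL", True),
            ]
        )
        assert find_dnam_near_variants(sel, dme_one, context_mode="and").empty
        got = find_dnam_near_variants(sel, dme_both, context_mode="and")
        assert set(got["cpg_id"]) == {"cg1"}

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(7)
        traits = ["HDL", "SBP", "TG"]
        expos = ["current smoking", "drinking habits"]
        sel_rows = [
            (
                f"rs{i}",
                f"chr{rng.integers(1, 3)}",
                int(rng.integers(1, 4_000_000)),
                traits[rng.integers(0, 3)],
                expos[rng.integers(0, 2)],
                "AA",
            )
            for i in range(40)
        ]
        dme_rows = [
            (
                f"cg{j}",
                f"chr{rng.integers(1, 3)}",
                int(rng.integers(1, 4_000_000)),
                (traits + expos)[rng.integers(0, 5)],
                bool(rng.random() < 0.7),
            )
            for j in range(60)
        ]
        sel = make_selected(sel_rows)
        dme = dme_frame(dme_rows)
        got = find_dnam_near_variants(sel, dme)
        expected = brute_force_pairs(
            sel.to_dict("records"),
            dme.rename(columns={"pos": "pos"}).to_dict("records"),
        )
        got_keys = set(zip(got["variant_id"], got["cpg_id"], got["context"]))
        exp_keys = {(v["variant_id"], c["cpg_id"], c["context"]) for v, c in expected}
        assert got_keys == exp_keys


class TestPrioritize:
    def test_toy_single_locus(self):
        sel = make_selected([("rs1", "chr1", 1_000_000, "HDL", "current smoking", "AA")])
        pairs = find_dnam_near_variants(
            sel, dme_frame([("cg1", "chr1", 1_100_000, "current smoking", True)])
        )
        loci = prioritize(
            pairs,
            eqtl_frame([("rs1", "g1", "Lung", True)]),
            eqtm_frame([("cg1", "g1", True)]),
        )
        assert len(loci) == 1
        row = loci.iloc[0]
        assert row["gene_id"] == "g1" and row["tier"] == "prioritized"
        assert row["n_variants"] == 1 and row["eqtl_tissues"] == ["Lung"]

    def test_eqtl_without_eqtm_is_not_prioritized(self):
        sel = make_selected([("rs1", "chr1", 1_000_000, "HDL", "current smoking", "AA")])
        pairs = find_dnam_near_variants(
            sel, dme_frame([("cg1", "chr1", 1_100_000, "current smoking", True)])
        )
        loci = prioritize(
            pairs,
            eqtl_frame([("rs1", "g1", "Lung", True)]),
            eqtm_frame([("cg1", "g1", False)]),
        )
        assert loci.empty

    def test_four_variants_aggregate_into_one_locus(self):
        sel = make_selected(
            [
                (f"rs{i}", "chr1", 1_000_000 + i * 10_000, "HDL", "current smoking", "AA")
                for i in range(4)
            ]
        )
        pairs = find_dnam_near_variants(
            sel, dme_frame([("cg1", "chr1", 1_100_000, "current smoking", True)])
        )
        loci = prioritize(
            pairs,
            eqtl_frame(
                [(f"rs{i}", "g1", t, True) for i, t in enumerate(
                    ["Artery Aorta", "Testis", "Artery Aorta", "Testis"]
                )]
            ),
            eqtm_frame([("cg1", "g1", True)]),
        )
        assert len(loci) == 1
        row = loci.iloc[0]
        assert row["n_variants"] == 4
        assert row["eqtl_tissues"] == ["Artery Aorta", "Testis"]

    def test_matches_brute_force_join(self):
        rng = np.random.default_rng(11)
        genes = [f"g{k}" for k in range(6)]
        sel_rows = [
            (
                f"rs{i}",
                "chr1",
                int(rng.integers(1, 3_000_000)),
                "HDL",
                "current smoking",
                "AA",
            )
            for i in range(15)
        ]
        dme_rows = [
            (
                f"cg{j}",
                "chr1",
                int(rng.integers(1, 3_000_000)),
                "current smoking",
                bool(rng.random() < 0.8),
            )
            for j in range(15)
        ]
        eqtl_rows = [
            (f"rs{rng.integers(0, 15)}", genes[rng.integers(0, 6)],
             ["Lung", "Liver"][rng.integers(0, 2)], bool(rng.random() < 0.7))
            for _ in range(30)
        ]
        eqtm_rows = [
            (f"cg{rng.integers(0, 15)}", genes[rng.integers(0, 6)],
             bool(rng.random() < 0.7))
            for _ in range(30)
        ]
        sel, dme = make_selected(sel_rows), dme_frame(dme_rows)
        eqtl, eqtm = eqtl_frame(eqtl_rows), eqtm_frame(eqtm_rows)
        got = prioritize(find_dnam_near_variants(sel, dme), eqtl, eqtm)
        expected = brute_force_prioritized(
            sel.to_dict("records"),
            dme.to_dict("records"),
            eqtl.to_dict("records"),
            eqtm.to_dict("records"),
        )
        got_map = {
            (r.gene_id, r.ancestry_group, r.trait, r.exposure): (
                set(r.variant_ids),
                set(r.cpg_ids),
                set(r.eqtl_tissues),
            )
            for r in got.itertuples()
        }
        assert got_map == expected


class TestFurtherPrioritize:
    def _prioritized(self, exposure):
        sel = make_selected([("rs1", "chr1", 1_000_000, "HDL", exposure, "AA")])
        pairs = find_dnam_near_variants(
            sel, dme_frame([("cg1", "chr1", 1_100_000, exposure, True)])
        )
        return prioritize(
            pairs,
            eqtl_frame([("rs1", "g1", "Lung", True)]),
            eqtm_frame([("cg1", "g1", True)]),
        )

    def test_smoking_class_matches_either_smoking_exposure(self):
        prio = self._prioritized("ever smoking")
        out = further_prioritize(prio, dexpr_frame([("g1", "smoking", True)]))
        assert len(out) == 1
        assert out.iloc[0]["tier"] == "further_prioritized"
        assert bool(out.iloc[0]["dexpr_flag"])

    def test_alcohol_locus_without_alcohol_dexpr_never_passes(self):
        prio = self._prioritized("current drinking")
        # only smoking expression evidence exists
        out = further_prioritize(prio, dexpr_frame([("g1", "smoking", True)]))
        assert out.empty

    def test_empty_prioritized_input(self):
        prio = self._prioritized("ever smoking").iloc[0:0]
        assert further_prioritize(prio, dexpr_frame([("g1", "smoking", True)])).empty

    def test_insignificant_dexpr_ignored(self):
        prio = self._prioritized("current smoking")
        out = further_prioritize(prio, dexpr_frame([("g1", "smoking", False)]))
        assert out.empty


class TestRunCascade:
    def _scenario(self, seed=5, n_causal=3):
        truth = default_truth(n_causal=n_causal)
        bundle = generate_evidence_tables(truth, seed=seed)
        with_signal = bundle.variants.loc[bundle.variants["has_gli_signal"]]
        sel = make_selected(
            [
                (v.variant_id, v.chrom, int(v.pos), "HDL", "current smoking", "AA")
                for v in with_signal.itertuples()
            ]
        )
        evidence = EvidenceTables(bundle.dme, bundle.eqtm, bundle.eqtl, bundle.dexpr)
        return truth, bundle, sel, evidence

    def test_scenario_recovers_exactly_the_causal_genes(self):
        truth, bundle, sel, evidence = self._scenario()
        loci, counts = run_cascade(sel, evidence, bundle.annotation)
        prio_genes = set(
            loci.loc[loci["tier"].isin(["prioritized", "further_prioritized"]), "gene_id"]
        )
        assert prio_genes == set(truth.causal_genes)
        assert counts["further_prioritized_genes"] == len(truth.causal_genes)
        # matches the brute-force join oracle
        expected = brute_force_prioritized(
            sel.to_dict("records"),
            bundle.dme.to_dict("records"),
            bundle.eqtl.to_dict("records"),
            bundle.eqtm.to_dict("records"),
        )
        assert {k[0] for k in expected} == set(truth.causal_genes)

    def test_decoys_never_reach_prioritized_over_replicates(self):
        for seed in range(8):
            truth, bundle, sel, evidence = self._scenario(seed=seed)
            loci, _ = run_cascade(sel, evidence, bundle.annotation)
            prio = loci.loc[loci["tier"] != "candidate", "gene_id"]
            assert set(prio) == set(truth.causal_genes)

    def test_eqtm_decoy_passes_pairing_but_not_prioritization(self):
        truth, bundle, sel, evidence = self._scenario()
        decoy = next(g for g, w in truth.decoy_genes.items() if w == "eQTM")
        pairs = find_dnam_near_variants(sel, bundle.dme)
        assert f"rs_{decoy}" in set(pairs["variant_id"])
        loci, _ = run_cascade(sel, evidence, bundle.annotation)
        tiers = loci.loc[loci["gene_id"] == decoy, "tier"]
        assert set(tiers) == {"candidate"}

    def test_removing_eqtm_table_collapses_prioritized_tier(self):
        truth, bundle, sel, evidence = self._scenario()
        evidence_no_eqtm = EvidenceTables(
            bundle.dme, bundle.eqtm.iloc[0:0], bundle.eqtl, bundle.dexpr
        )
        loci, counts = run_cascade(sel, evidence_no_eqtm, bundle.annotation)
        assert counts["prioritized_loci"] == 0
        assert set(loci["tier"]) <= {"candidate"}

    def test_empty_truth_empty_cascade(self):
        truth = ScenarioTruth(frozenset(), {}, {})
        bundle = generate_evidence_tables(truth, seed=1, n_noise_rows=0)
        sel = make_selected([])
        evidence = EvidenceTables(bundle.dme, bundle.eqtm, bundle.eqtl, bundle.dexpr)
        loci, counts = run_cascade(sel, evidence, bundle.annotation)
        assert loci.empty
        assert counts["prioritized_loci"] == 0

    def test_tier_nesting_per_context(self):
        truth, bundle, sel, evidence = self._scenario()
        loci, _ = run_cascade(sel, evidence, bundle.annotation)
        for key in ["ancestry_group", "trait", "exposure"]:
            assert key in loci.columns
        further = set(loci.loc[loci["tier"] == "further_prioritized", "gene_id"])
        cand_or_above = set(loci["gene_id"])
        assert further <= cand_or_above

    def test_monotone_in_evidence_rows(self):
        truth, bundle, sel, evidence = self._scenario()
        loci_full, _ = run_cascade(sel, evidence, bundle.annotation)
        reduced = EvidenceTables(
            bundle.dme, bundle.eqtm.iloc[:-2], bundle.eqtl, bundle.dexpr
        )
        loci_red, _ = run_cascade(sel, reduced, bundle.annotation)
        full_prio = set(
            loci_full.loc[loci_full["tier"] != "candidate", "gene_id"]
        )
        red_prio = set(loci_red.loc[loci_red["tier"] != "candidate", "gene_id"])
        assert red_prio <= full_prio

    def test_rerun_is_byte_identical(self, tmp_path):
        truth, bundle, sel, evidence = self._scenario()
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        loci1, _ = run_cascade(sel, evidence, bundle.annotation)
        loci2, _ = run_cascade(sel, evidence, bundle.annotation)
        loci_to_tsv(loci1, p1)
        loci_to_tsv(loci2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_loci_tsv_round_trip(self, tmp_path):
        truth, bundle, sel, evidence = self._scenario()
        loci, _ = run_cascade(sel, evidence, bundle.annotation)
        path = tmp_path / "loci.tsv"
        loci_to_tsv(loci, path)
        back = loci_from_tsv(path)
        assert list(back["gene_id"]) == list(loci["gene_id"])
        assert list(back["variant_ids"]) == list(loci["variant_ids"])

    def test_context_discipline(self):
        truth, bundle, sel, evidence = self._scenario()
        loci, _ = run_cascade(sel, evidence, bundle.annotation)
        sel_contexts = set(zip(sel["trait"], sel["exposure"], sel["ancestry_group"]))
        for r in loci.itertuples():
            assert (r.trait, r.exposure, r.ancestry_group) in sel_contexts
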