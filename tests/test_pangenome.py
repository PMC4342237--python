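"""Pan/core set algebra against explicit membership-list oracles."""

import numpy as np
import pytest

from mycopan import (
    FamilyAnnotation,
    ValidationError,
    cluster_genomes_by_profile,
    cog_profile,
    core_venn,
    filter_expressed,
    functional_breakdown,
    group_pan_core,
    hgt_contribution,
    pan_core,
    progressive_curve,
    unique_genes,
)

from conftest import brute_pan_core, brute_venn, make_matrix, random_matrix


class TestPanCore:
    def test_single_genome_pan_equals_core(self):
        m = make_matrix({f"f{i}": {"gA": 1} for i in range(5)})
        r = pan_core(m, ["gA"])
        assert r.pan_size == r.core_size == 5
        assert r.dispensable_size == 0

    def test_disjoint_family_sets(self):
        m = make_matrix(
            {**{f"a{i}": {"gA": 1, "gB": 0} for i in range(3)},
             **{f"b{i}": {"gA": 0, "gB": 1} for i in range(4)}})
        r = pan_core(m, ["gA", "gB"])
        assert r.pan_size == 7
        assert r.core_size == 0

    def test_unknown_genome_named(self):
        m = make_matrix({"f1": {"gA": 1}})
        with pytest.raises(ValidationError, match="gX"):
            pan_core(m, ["gA", "gX"])

    def test_empty_set_rejected(self):
        m = make_matrix({"f1": {"gA": 1}})
        with pytest.raises(ValidationError):
            pan_core(m, [])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = random_matrix(rng, 200, 8)
        genomes = list(rng.choice(m.genome_ids, size=5, replace=False))
        r = pan_core(m, genomes)
        pan, core = brute_pan_core(m, genomes)
        assert set(r.pan_families) == pan
        assert set(r.core_families) == core
        assert set(r.dispensable_families) == pan - core


class TestProgressiveCurve:
    def test_single_genome_step(self):
        m = make_matrix({f"f{i}": {"gA": 1, "gB": 0} for i in range(4)})
        c = progressive_curve(m, ["gA"])
        step = c.steps.iloc[0]
        assert step["pan_size"] == step["core_size"] == step["new_families"] == 4

    def test_identical_genome_adds_nothing(self):
        m = make_matrix({f"f{i}": {"gA": 1, "gB": 1} for i in range(6)})
        c = progressive_curve(m, ["gA", "gB"])
        last = c.steps.iloc[-1]
        assert last["new_families"] == 0
        assert last["pan_size"] == 6 and last["core_size"] == 6

    def test_repeated_genome_rejected(self):
        m = make_matrix({"f1": {"gA": 1}})
        with pytest.raises(ValidationError, match="gA"):
            progressive_curve(m, ["gA", "gA"])

    def test_prefix_consistency_and_monotonicity(self):
        rng = np.random.default_rng(3)
        m = random_matrix(rng, 120, 6)
        order = list(m.genome_ids)
        c = progressive_curve(m, order)
        prev_pan, prev_core = 0, None
        for k in range(1, len(order) + 1):
            r = pan_core(m, order[:k])
            row = c.steps.loc[k]
            assert row["pan_size"] == r.pan_size
            assert row["core_size"] == r.core_size
            assert row["pan_size"] >= prev_pan
            assert prev_core is None or row["core_size"] <= prev_core
            assert row["new_families"] == r.pan_size - prev_pan
            prev_pan, prev_core = row["pan_size"], row["core_size"]


class TestGroupPanCore:
    def test_whole_table_equals_full_pan_core(self):
        rng = np.random.default_rng(4)
        m = random_matrix(rng, 100, 6)
        from mycopan import assign_phenotypes
        phen = assign_phenotypes(
            m, {"RCP": [m.family_ids[0]]},
            {g: "FL" for g in m.genome_ids})
        # every genome has some lifestyle value; group over it == all genomes
        r = group_pan_core(m, phen, "lifestyle", "FL")
        full = pan_core(m, m.genome_ids)
        assert r.pan_families == full.pan_families
        assert r.core_families == full.core_families

    def test_group_equals_explicit_member_set(self, table1):
        rng = np.random.default_rng(5)
        strains = table1.strains[:10]
        m = random_matrix(rng, 150, 10)
        m = make_matrix({
            f: {s: int(m.counts.iloc[i, j]) for j, s in enumerate(strains)}
            for i, f in enumerate(m.family_ids)})
        members = table1.group("growth_rate", "slow") & set(strains)
        r = group_pan_core(m, table1, "growth_rate", "slow")
        expected = pan_core(m, members)
        assert r.pan_families == expected.pan_families
        assert r.core_families == expected.core_families

    def test_fixed_family_in_group_core(self, table1):
        degraders = sorted(table1.group("pah_metabolism", "degrading"))
        others = sorted(table1.group("pah_metabolism", "non-degrading"))[:4]
        m = make_matrix({
            "nid": {**{s: 1 for s in degraders}, **{s: 0 for s in others}},
            "noise": {**{s: 0 for s in degraders[:3]},
                      **{s: 1 for s in degraders[3:] + others}},
        })
        r = group_pan_core(m, table1, "pah_metabolism", "degrading")
        assert "nid" in r.core_families

    def test_empty_group_names_it(self, table1):
        m = make_matrix({"f1": {"not_a_strain": 1}})
        with pytest.raises(ValidationError, match="degrading"):
            group_pan_core(m, table1, "pah_metabolism", "degrading")


class TestCoreVenn:
    def test_identical_groups_only_central_region(self):
        m = make_matrix({f"f{i}": {"gA": 1, "gB": 1} for i in range(5)})
        regions = core_venn(m, {"X": ["gA", "gB"], "Y": ["gA", "gB"]})
        assert regions[("X", "Y")] == 5
        assert regions[("X",)] == regions[("Y",)] == 0

    def test_disjoint_cores_only_exclusive_regions(self):
        m = make_matrix(
            {**{f"a{i}": {"gA": 1, "gB": 0} for i in range(2)},
             **{f"b{i}": {"gA": 0, "gB": 1} for i in range(3)}})
        regions = core_venn(m, {"X": ["gA"], "Y": ["gB"]})
        assert regions[("X",)] == 2 and regions[("Y",)] == 3
        assert regions[("X", "Y")] == 0

    def test_more_than_three_groups_rejected(self):
        m = make_matrix({"f1": {"gA": 1, "gB": 1, "gC": 1, "gD": 1}})
        with pytest.raises(ValidationError, match="2 or 3"):
            core_venn(m, {n: [g] for n, g in
                          zip("WXYZ", ["gA", "gB", "gC", "gD"])})

    @pytest.mark.parametrize("seed", range(8))
    def test_three_group_regions_match_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        m = random_matrix(rng, 150, 9)
        groups = {"X": m.genome_ids[0:3], "Y": m.genome_ids[3:6],
                  "Z": m.genome_ids[6:9]}
        regions = core_venn(m, groups)
        cores = {n: set(pan_core(m, g).core_families) for n, g in groups.items()}
        expected = brute_venn(cores)
        for key, count in regions.items():
            assert count == expected.get(key, 0), key
        assert sum(regions.values()) == len(set().union(*cores.values()))


class TestUniqueGenes:
    def test_family_leaking_into_background_excluded(self):
        m = make_matrix({"f1": {"gA": 1, "gB": 1, "gC": 1},
                         "f2": {"gA": 1, "gB": 1, "gC": 0}})
        assert unique_genes(m, ["gA", "gB"], ["gC"]) == {"f2"}

    def test_overlapping_groups_rejected(self):
        m = make_matrix({"f1": {"gA": 1, "gB": 1}})
        with pytest.raises(ValidationError, match="gA"):
            unique_genes(m, ["gA"], ["gA", "gB"])

    def test_planted_unique_module_recovered_exactly(self):
        rng = np.random.default_rng(77)
        focal = [f"d{i}" for i in range(4)]
        background = [f"n{i}" for i in range(6)]
        module = {f"uniq{i}": {**{g: 1 for g in focal},
                               **{g: 0 for g in background}}
                  for i in range(12)}
        noise = {}
        for i in range(200):
            # noise families never satisfy (core focal & absent background)
            row = {g: int(rng.random() < 0.5) for g in focal + background}
            if all(row[g] for g in focal) and not any(row[g] for g in background):
                row[background[0]] = 1
            noise[f"noise{i}"] = row
        m = make_matrix({**module, **noise})
        found = unique_genes(m, focal, background)
        assert found == set(module)

    def test_invariants_against_pan_core(self):
        rng = np.random.default_rng(8)
        m = random_matrix(rng, 150, 8)
        focal, background = m.genome_ids[:3], m.genome_ids[3:]
        u = unique_genes(m, focal, background)
        assert u <= pan_core(m, focal).core_families
        assert not (u & pan_core(m, background).pan_families)


@pytest.fixture
def planted_annotation():
    records = {}
    for i in range(18):
        records[f"r{i}"] = {"functional_module": "RCP"}
    for i in range(12):
        records[f"s{i}"] = {"functional_module": "SCP"}
    for i in range(4):
        records[f"c{i}"] = {"functional_module": "CAP"}
    return FamilyAnnotation.from_records(records)


class TestFunctionalBreakdown:
    def test_all_one_module(self):
        ann = FamilyAnnotation.from_records(
            {f"f{i}": {"functional_module": "RCP"} for i in range(3)})
        ct = functional_breakdown([f"f{i}" for i in range(3)], ann,
                                  by="functional_module")
        assert ct.table["count"].to_dict() == {"RCP": 3}

    def test_planted_module_proportions(self, planted_annotation):
        fams = list(planted_annotation.table.index)
        ct = functional_breakdown(fams, planted_annotation, by="functional_module")
        props = ct.proportions()["count"]
        assert round(props["RCP"]) == 53
        assert round(props["SCP"]) == 35
        assert round(props["CAP"]) == 12

    def test_multilabel_cog_counts_match_direct_iteration(self):
        rng = np.random.default_rng(21)
        letters = "CEFGHI"
        records = {}
        for i in range(60):
            n = int(rng.integers(0, 3))
            ls = "".join(rng.choice(list(letters), size=n, replace=False))
            records[f"f{i}"] = {"cog_categories": ls}
        ann = FamilyAnnotation.from_records(records)
        fams = list(records)
        ct = functional_breakdown(fams, ann, by="cog_category")
        direct = sum(max(1, len(set(records[f]["cog_categories"]))) for f in fams)
        assert ct.cell_total == direct
        assert ct.n_families == 60

    def test_unannotated_labelled_poorly_characterized(self):
        ann = FamilyAnnotation.from_records({})
        ct = functional_breakdown(["f1", "f2"], ann, by="cog_category")
        assert ct.table["count"].to_dict() == {"poorly characterized": 2}


class TestHgtContribution:
    def test_all_hgt_and_fixed_goes_to_hgt_core(self):
        m = make_matrix({f"f{i}": {"gA": 1, "gB": 1} for i in range(5)})
        ann = FamilyAnnotation.from_records(
            {f"f{i}": {"hgt": True} for i in range(5)})
        ct = hgt_contribution(m, ann, ["gA", "gB"])
        assert ct.table.at["hgt", "core"] == 5
        assert ct.cell_total == 5

    def test_no_flags_hgt_row_zero(self):
        m = make_matrix({f"f{i}": {"gA": 1, "gB": i % 2} for i in range(6)})
        ct = hgt_contribution(m, FamilyAnnotation.from_records({}), ["gA", "gB"])
        assert ct.table.loc["hgt"].sum() == 0
        assert ct.cell_total == 6

    def test_random_flags_match_direct_classification(self):
        rng = np.random.default_rng(9)
        m = random_matrix(rng, 120, 5)
        flags = {f: bool(rng.random() < 0.3) for f in m.family_ids}
        ann = FamilyAnnotation.from_records(
            {f: {"hgt": v} for f, v in flags.items()})
        ct = hgt_contribution(m, ann, m.genome_ids)
        r = pan_core(m, m.genome_ids)
        for f in r.pan_families:
            row = "hgt" if flags[f] else "non-hgt"
            col = "core" if f in r.core_families else "dispensable"
            assert ct.table.at[row, col] >= 1  # cell populated
        direct = sum(1 for f in r.pan_families if flags[f] and f in r.core_families)
        assert ct.table.at["hgt", "core"] == direct
        assert ct.cell_total == r.pan_size


class TestFilterExpressed:
    def test_no_flags_empty(self):
        assert filter_expressed(["f1"], FamilyAnnotation.from_records({})) == frozenset()

    def test_all_flagged_identity(self):
        ann = FamilyAnnotation.from_records(
            {f"f{i}": {"expressed": True} for i in range(4)})
        fams = [f"f{i}" for i in range(4)]
        assert filter_expressed(fams, ann) == frozenset(fams)

    def test_planted_113_of_136(self):
        records = {f"f{i}": {"expressed": i < 113} for i in range(136)}
        ann = FamilyAnnotation.from_records(records)
        assert len(filter_expressed(records, ann)) == 113


class TestCogProfile:
    def test_multilabel_tally(self):
        m = make_matrix({"f1": {"gA": 1}, "f2": {"gA": 1}})
        ann = FamilyAnnotation.from_records(
            {"f1": {"cog_categories": "C"}, "f2": {"cog_categories": "CE"}})
        prof = cog_profile(m, ann)
        assert prof.loc["gA", "C"] == 2
        assert prof.loc["gA", "E"] == 1

    def test_empty_annotation_all_zero(self):
        m = make_matrix({"f1": {"gA": 1, "gB": 0}})
        prof = cog_profile(m, FamilyAnnotation.from_records({}))
        assert prof.shape == (2, 0) or (prof.to_numpy() == 0).all()

    def test_random_instance_equals_direct_tally(self):
        rng = np.random.default_rng(31)
        m = random_matrix(rng, 80, 4)
        records = {}
        for f in m.family_ids:
            n = int(rng.integers(0, 3))
            records[f] = {"cog_categories":
                          "".join(rng.choice(list("CDEKLM"), n, replace=False))}
        ann = FamilyAnnotation.from_records(records)
        prof = cog_profile(m, ann)
        for g in m.genome_ids:
            for c in prof.columns:
                direct = sum(
                    1 for f in m.family_ids
                    if m.counts.at[f, g] >= 1 and c in records[f]["cog_categories"])
                assert prof.at[g, c] == direct


class TestClusterGenomes:
    def test_identical_genomes_merge_at_height_zero(self):
        m = make_matrix({f"f{i}": {"gA": 1, "gB": 1, "gC": 0} for i in range(5)})
        clust = cluster_genomes_by_profile(m)
        assert min(clust.merge_heights()) == pytest.approx(0.0)

    def test_identical_pair_merges_first(self):
        m = make_matrix({"f1": {"gA": 1, "gB": 1, "gC": 0},
                         "f2": {"gA": 0, "gB": 0, "gC": 1}})
        clust = cluster_genomes_by_profile(m)
        first = clust.linkage[0]
        merged = {clust.genome_ids[int(first[0])], clust.genome_ids[int(first[1])]}
        assert merged == {"gA", "gB"}

    def test_planted_block_groups_together(self):
        rng = np.random.default_rng(13)
        groupA = [f"a{i}" for i in range(4)]
        groupB = [f"b{i}" for i in range(4)]
        data = {}
        for i in range(30):
            data[f"mod{i}"] = {**{g: 1 for g in groupA}, **{g: 0 for g in groupB}}
        for i in range(10):
            data[f"bg{i}"] = {g: int(rng.random() < 0.5) for g in groupA + groupB}
        m = make_matrix(data)
        clust = cluster_genomes_by_profile(m)
        order = list(clust.leaf_order)
        positions = sorted(order.index(g) for g in groupA)
        assert positions == list(range(positions[0], positions[0] + 4))

    def test_single_genome_rejected(self):
        m = make_matrix({"f1": {"gA": 1}})
        with pytest.raises(ValidationError):
            cluster_genomes_by_profile(m)
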