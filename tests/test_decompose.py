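"""Gene-family decomposition: SCC, LSD, TSD, SE, MI, MO, one-paralog."""

import pytest

import orthodelta as od
from orthodelta import FilterConfig, GeneFamily, MIConfig
from orthodelta._util import tips_of


def fam(newick, lengths=None, fid="f1"):
    return GeneFamily(
        tree=od.parse_newick(newick),
        smap=od.SpeciesMap.from_delimiter("|"),
        lengths=lengths,
        family_id=fid,
    )


def members(sets):
    return {frozenset(s.members) for s in sets}


def species_of(family, names):
    return [family.smap(n) for n in names]


def se_bruteforce(family, min_taxa):
    """Independent oracle: enumerate every rooted subtree of the trimmed
    tree, keep the duplicate-free ones, select the maximal by containment,
    then apply the occupancy threshold."""
    trimmed = od.trim_tsd(family)
    smap = trimmed.smap
    dupfree = []
    for node in trimmed.tree.postorder(include_self=True):
        leaves = [t.name for t in tips_of(node)]
        sps = species_of(trimmed, leaves)
        if len(sps) == len(set(sps)):
            dupfree.append(frozenset(leaves))
    maximal = {s for s in dupfree if not any(s < t for t in dupfree)}
    return {
        s for s in maximal if len({smap(x) for x in s}) >= min_taxa
    }


# ---------------------------------------------------------------------------
# SCC
# ---------------------------------------------------------------------------

def test_scc_keeps_single_copy_families():
    f = fam("((a|1:1,b|1:1):1,(c|1:1,(d|1:1,e|1:1):1):1);")
    kept = od.filter_scc(f, FilterConfig(min_taxa=4))
    assert kept is not None and kept.method == "SCC"
    assert sorted(kept.members) == sorted(f.copies())


def test_scc_rejects_duplicates_and_low_occupancy():
    dup = fam("((a|1:1,a|2:1):1,(b|1:1,c|1:1):1);")
    assert od.filter_scc(dup, FilterConfig(min_taxa=2)) is None
    small = fam("((a|1:1,b|1:1):1,c|1:1);")
    assert od.filter_scc(small, FilterConfig(min_taxa=4)) is None


# ---------------------------------------------------------------------------
# LSD
# ---------------------------------------------------------------------------

def test_lsd_median_length_survivor_tie_broken_by_tree_order():
    f = fam(
        "((A|1:1,A|2:1):1,B|1:1);",
        lengths={"A|1": 300, "A|2": 200, "B|1": 250},
    )
    out = od.trim_lsd(f)
    # median length is 250; |300-250| == |200-250|, tie -> first in tree
    assert sorted(out.copies()) == ["A|1", "B|1"]
    assert out.removed == ["A|2"]


def test_lsd_nested_duplicates_reduced_to_one_copy():
    f = fam("(((A|1:1,A|2:1):1,A|3:1):1,B|1:1);")
    out = od.trim_lsd(f)
    assert len([c for c in out.copies() if c.startswith("A")]) == 1


def test_lsd_no_duplicates_identity(dl_families):
    f = fam("((a|1:1,b|1:1):1,c|1:1);")
    assert sorted(od.trim_lsd(f).copies()) == sorted(f.copies())


def test_lsd_tsd_idempotent_and_only_remove(dl_families):
    for f in dl_families[:60]:
        once = od.trim_lsd(f.family)
        assert set(once.copies()) <= set(f.family.copies())
        assert set(od.trim_lsd(once).copies()) == set(once.copies())
        tsd = od.trim_tsd(f.family)
        assert set(tsd.copies()) <= set(f.family.copies())
        assert set(od.trim_tsd(tsd).copies()) == set(tsd.copies())


# ---------------------------------------------------------------------------
# TSD
# ---------------------------------------------------------------------------

def test_tsd_keeps_minimum_distance_cross_pair():
    f = fam("((A|1:1,B|1:1):1,(A|2:5,B|2:5):1);")
    out = od.trim_tsd(f)
    assert sorted(out.copies()) == ["A|1", "B|1"]


def test_tsd_three_copy_clade():
    f = fam("((A|1:1,B|1:1):1,A|2:3);")
    out = od.trim_tsd(f)
    assert sorted(out.copies()) == ["A|1", "B|1"]


def test_tsd_untouched_without_two_species_clade():
    f = fam("((a|1:1,b|1:1):1,(c|1:1,d|1:1):1);")
    assert sorted(od.trim_tsd(f).copies()) == sorted(f.copies())


# ---------------------------------------------------------------------------
# SE
# ---------------------------------------------------------------------------

def test_se_whole_tree_when_duplicate_free():
    f = fam("((a|1:1,b|1:1):1,(c|1:1,d|1:1):1);")
    sets = od.extract_se(f, FilterConfig(min_taxa=4))
    assert members(sets) == {frozenset(f.copies())}


def test_se_splits_at_duplication():
    f = fam("(((A|1,B|1),(A|2,C|1)),D|1);")
    sets = od.extract_se(f, FilterConfig(min_taxa=2))
    assert members(sets) == {
        frozenset({"A|1", "B|1"}),
        frozenset({"A|2", "C|1"}),
    }


def test_se_matches_bruteforce(dl_families):
    cfg = FilterConfig(min_taxa=4)
    for f in dl_families[:100]:
        assert members(od.extract_se(f.family, cfg)) == se_bruteforce(
            f.family, cfg.min_taxa
        )


# ---------------------------------------------------------------------------
# MI
# ---------------------------------------------------------------------------

def test_mi_whole_tree_when_duplicate_free():
    f = fam("((a|1:1,b|1:1):1,(c|1:1,d|1:1):1);")
    sets = od.extract_mi(f, MIConfig(min_taxa=4))
    assert members(sets) == {frozenset(f.copies())}


def test_mi_iterative_extraction_reanalyzes_remainder():
    f = fam("(((A|1,B|1),(A|2,C|1)),D|1);")
    sets = od.extract_mi(f, MIConfig(min_taxa=2))
    # the largest duplicate-free clade {A|1,B|1} is cut first; the remainder
    # ((A|2,C|1),D|1) is then duplicate-free and emitted whole
    assert members(sets) == {
        frozenset({"A|1", "B|1"}),
        frozenset({"A|2", "C|1", "D|1"}),
    }


def test_mi_long_branch_cut_excludes_leaf():
    f = fam("((a|1:0.1,b|1:0.1):0.1,(c|1:0.1,d|1:0.5):0.1);")
    sets = od.extract_mi(f, MIConfig(min_taxa=2, long_branch_cutoff=0.4))
    assert all("d|1" not in s.members for s in sets)
    assert members(sets) == {frozenset({"a|1", "b|1", "c|1"})}


def test_mi_cutoff_requires_lengths():
    f = fam("(((A|1,B|1),(A|2,C|1)),D|1);")
    with pytest.raises(od.TreeError):
        od.extract_mi(f, MIConfig(min_taxa=2, long_branch_cutoff=0.4))


# ---------------------------------------------------------------------------
# MO
# ---------------------------------------------------------------------------

def test_mo_requires_monophyletic_outgroup():
    f = fam("(((a|1:1,o|1:1):1,(o|2:1,b|1:1):1):1,c|1:1);")
    assert od.extract_mo(f, {"o"}, FilterConfig(min_taxa=2)) is None


def test_mo_requires_outgroup_presence_and_single_copy():
    f = fam("((a|1:1,b|1:1):1,c|1:1);")
    assert od.extract_mo(f, {"z"}, FilterConfig(min_taxa=2)) is None
    f2 = fam("((o|1:1,o|2:1):1,(a|1:1,b|1:1):1);")
    assert od.extract_mo(f2, {"o"}, FilterConfig(min_taxa=2)) is None


def test_mo_duplication_free_returns_full_ingroup():
    f = fam("((o|1:1,o2|1:1):1,((a|1:1,b|1:1):1,c|1:1):1);")
    out = od.extract_mo(f, {"o", "o2"}, FilterConfig(min_taxa=3))
    assert sorted(out.members) == ["a|1", "b|1", "c|1"]


def test_mo_keeps_larger_side_of_duplication():
    # ingroup root joins a 2-species and a 4-species subtree sharing 'a'
    f = fam(
        "(o|1:1,((a|1:1,b|1:1):1,((a|2:1,c|1:1):1,(d|1:1,e|1:1):1):1):1);"
    )
    out = od.extract_mo(f, {"o"}, FilterConfig(min_taxa=3))
    assert sorted(out.members) == ["a|2", "c|1", "d|1", "e|1"]


# ---------------------------------------------------------------------------
# One paralog
# ---------------------------------------------------------------------------

def test_one_paralog_deterministic_and_single_copy(dl_families):
    cfg = FilterConfig(min_taxa=4)
    for f in dl_families[:30]:
        a = od.sample_one_paralog(f.family, cfg, seed=5)
        b = od.sample_one_paralog(f.family, cfg, seed=5)
        if a is None:
            assert b is None
            continue
        assert a.members == b.members
        sps = species_of(f.family, a.members)
        assert len(sps) == len(set(sps))
        # forced choice for single-copy species
        by_sp = {}
        for c in f.family.copies():
            by_sp.setdefault(f.family.smap(c), []).append(c)
        for sp, copies in by_sp.items():
            if len(copies) == 1:
                assert copies[0] in a.members


def test_one_paralog_occupancy_gate():
    f = fam("((a|1:1,a|2:1):1,b|1:1);")
    assert od.sample_one_paralog(f, FilterConfig(min_taxa=4), seed=1) is None


# ---------------------------------------------------------------------------
# Cross-method invariants
# ---------------------------------------------------------------------------

def test_no_method_emits_a_species_twice(dl_families):
    cfg = FilterConfig(min_taxa=4)
    micfg = MIConfig(min_taxa=4)
    for f in dl_families[:120]:
        outputs = []
        outputs.extend(od.extract_se(f.family, cfg))
        outputs.extend(od.extract_mi(f.family, micfg))
        mo = od.extract_mo(f.family, {"s01"}, cfg)
        if mo:
            outputs.append(mo)
        one = od.sample_one_paralog(f.family, cfg, seed=9)
        if one:
            outputs.append(one)
        scc = od.filter_scc(f.family, cfg)
        if scc:
            outputs.append(scc)
        for s in outputs:
            sps = species_of(f.family, s.members)
            assert len(sps) == len(set(sps)), (f.family.family_id, s.method)


def test_null_process_families_pass_through(stree12):
    cfg0 = od.SimConfig(n_species=12, dup_rate=0.0, loss_rate=0.0, seed=2)
    f = od.sim_dl_family(stree12, cfg0, "null").family
    allc = set(f.copies())
    fc = FilterConfig(min_taxa=4)
    assert set(od.filter_scc(f, fc).members) == allc
    assert set(od.trim_lsd(f).copies()) == allc
    assert set(od.trim_tsd(f).copies()) == allc
    assert members(od.extract_se(f, fc)) == {frozenset(allc)}
    assert members(od.extract_mi(f, MIConfig(min_taxa=4))) == {frozenset(allc)}
    og_sp = f.smap(min(allc))
    mo = od.extract_mo(f, {og_sp}, fc)
    assert set(mo.members) == {c for c in allc if f.smap(c) != og_sp}


def test_se_recovers_true_ortholog_groups(dl_families):
    """Every true group surviving LSD/TSD trimming with >= min_taxa species
    appears inside a single SE set."""
    cfg = FilterConfig(min_taxa=4)
    checked = 0
    for f in dl_families[:120]:
        truth = od.true_ortholog_sets(f, 2)
        surviving = set(od.trim_tsd(f.family).copies())
        se_sets = [set(s.members) for s in od.extract_se(f.family, cfg)]
        for grp in truth:
            g = set(grp) & surviving
            if len({f.family.smap(c) for c in g}) < cfg.min_taxa:
                continue
            checked += 1
            assert any(g <= s for s in se_sets)
    assert checked > 20


# ---------------------------------------------------------------------------
# Accounting
# ---------------------------------------------------------------------------

def test_family_stats_arithmetic():
    f3 = fam("((a|1:1,b|1:1):1,c|1:1);", fid="f3")
    f5 = fam("(((a|1:1,a|2:1):1,(b|1:1,c|1:1):1):1,d|1:1);", fid="f5")
    stats = od.family_stats([f3, f5])
    assert stats.n_families == 2 and stats.n_copies == 8
    assert stats.mean_copies == pytest.approx(4.0)
    assert stats.mean_copies_rounded == 4
    assert stats.occupancy == {"a": 2, "b": 2, "c": 2, "d": 1}
    single = od.family_stats([f3])
    assert single.mean_copies == pytest.approx(3.0)
    with pytest.raises(ValueError):
        od.family_stats([])
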