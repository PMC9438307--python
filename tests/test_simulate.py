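import numpy as np
import pytest

from olfevo.io import FastaRecord
from olfevo.simulate import (
    emit_genomes,
    make_reference_panel,
    simulate_coevolving_families,
    simulate_family_counts,
    simulate_lamellae,
    simulate_species_tree,
    validate_trait_table,
)
from olfevo.simulate.genomes import STOP_CODONS
from olfevo.simulate.panel import mutate_cds, random_cds
from olfevo.trees import TimeTree


# ------------------------------------------------------------ species trees

def test_two_taxon_cherry():
    t = simulate_species_tree(2, 42.0, seed=0)
    assert len(t.leaves()) == 2
    depths = t.depths()
    assert all(abs(depths[l] - 42.0) < 1e-9 for l in t.leaves())


def test_species_tree_deterministic():
    a = simulate_species_tree(9, 100.0, seed=5).to_newick()
    b = simulate_species_tree(9, 100.0, seed=5).to_newick()
    assert a == b


def test_species_tree_rejects_tiny():
    with pytest.raises(ValueError):
        simulate_species_tree(1, 10.0)


def test_many_trees_ultrametric_binary():
    rng = np.random.default_rng(33)
    for _ in range(1000):
        t = simulate_species_tree(10, 50.0, rng=rng)
        assert t.is_ultrametric()
        assert t.is_binary()


# --------------------------------------------------------- family histories

def test_zero_rates_constant_counts(small_tree):
    h = simulate_family_counts(small_tree, 0.0, 0.0, 7, seed=1)
    assert all(v == 7 for v in h.counts.values())
    assert h.total_events() == (0, 0)


def test_zero_root_count(small_tree):
    h = simulate_family_counts(small_tree, 0.02, 0.01, 0, seed=1)
    assert all(v == 0 for v in h.counts.values())
    assert h.total_events() == (0, 0)
    assert h.gene_trees() == []


def test_negative_rates_rejected(small_tree):
    with pytest.raises(ValueError):
        simulate_family_counts(small_tree, -0.1, 0.0, 1)


def test_bookkeeping_holds_on_random_histories(small_tree):
    rng = np.random.default_rng(8)
    for _ in range(50):
        h = simulate_family_counts(small_tree, 0.01, 0.008, 5, rng=rng)
        h.check_bookkeeping()  # raises on violation


@pytest.mark.parametrize("b,d", [(0.01, 0.005), (0.005, 0.005), (0.002, 0.008)])
def test_neutral_expectation(b, d):
    # linear birth-death: E[N_T] = N0 * exp((b - d) * T)
    tree = TimeTree.from_newick("(A:100,B:100);")
    rng = np.random.default_rng(123)
    n0, reps = 20, 3000
    tips = [simulate_family_counts(tree, b, d, n0, rng=rng).tip_counts()["A"]
            for _ in range(reps)]
    mean = np.mean(tips)
    se = np.std(tips) / np.sqrt(reps)
    expect = n0 * np.exp((b - d) * 100.0)
    assert abs(mean - expect) <= 3.0 * se


def test_gene_tree_leaf_counts_match_tips(small_tree):
    h = simulate_family_counts(small_tree, 0.01, 0.004, 6, seed=3)
    leaves = [name for gt in h.gene_trees() for name in gt.leaf_names()]
    per_species = {sp: 0 for sp in small_tree.leaf_names()}
    for name in leaves:
        per_species[name.split("|")[0]] += 1
    assert per_species == h.tip_counts()


# ------------------------------------------------------ coevolving families

def test_sd_zero_multipliers_all_one(small_tree):
    hs = simulate_coevolving_families(small_tree, shared_multiplier_sd=0.0, seed=4)
    for fam in ("OR", "TAAR", "OlfC"):
        assert all(m == (1.0, 1.0) for m in hs[fam].multipliers.values())


def test_ora_dampening_zero_pins_multiplier(small_tree):
    hs = simulate_coevolving_families(
        small_tree, shared_multiplier_sd=0.8, ora_dampening=0.0, seed=4
    )
    assert all(mb == 1.0 and md == 1.0 for mb, md in hs["ORA"].multipliers.values())


def test_shared_multiplier_correlates_gains():
    from olfevo.comparative import branch_correlation

    rng = np.random.default_rng(2)
    tree = simulate_species_tree(40, 100.0, rng=rng)
    branches = [n for n in tree.preorder() if n.parent is not None]
    positive = total = 0
    for _ in range(40):
        hs = simulate_coevolving_families(tree, shared_multiplier_sd=0.8, rng=rng)
        go = [hs["OR"].gains(n) for n in branches]
        gt = [hs["TAAR"].gains(n) for n in branches]
        try:
            r, _ = branch_correlation(go, gt)
        except ValueError:
            continue
        total += 1
        positive += r > 0
    assert total >= 30
    assert positive / total >= 0.95


# ----------------------------------------------------------------- genomes

def test_emit_all_clean_genes(panel):
    rng = np.random.default_rng(10)
    tree = simulate_species_tree(2, 80.0, rng=rng)
    hs = simulate_coevolving_families(
        tree, root_counts={"OR": 3, "TAAR": 2, "OlfC": 1, "ORA": 1}, rng=rng
    )
    genomes, truth = emit_genomes(hs, panel, pseudo_fraction=0.0,
                                  truncated_fraction=0.0, edge_fraction=0.0, rng=rng)
    assert set(truth["status"]) <= {"gene"}
    assert (truth["n_lof"] == 0).all()


def test_emit_all_pseudogenes(panel):
    rng = np.random.default_rng(11)
    tree = simulate_species_tree(2, 80.0, rng=rng)
    hs = simulate_coevolving_families(
        tree, root_counts={"OR": 3, "TAAR": 2, "OlfC": 1, "ORA": 1}, rng=rng
    )
    genomes, truth = emit_genomes(hs, panel, pseudo_fraction=1.0, rng=rng)
    assert set(truth["status"]) <= {"pseudogene"}
    assert (truth["n_lof"] >= 1).all()


def test_emit_deterministic(panel):
    def build():
        rng = np.random.default_rng(5)
        tree = simulate_species_tree(2, 80.0, rng=rng)
        hs = simulate_coevolving_families(
            tree, root_counts={"OR": 2, "TAAR": 2, "OlfC": 1, "ORA": 1}, rng=rng
        )
        return emit_genomes(hs, panel, pseudo_fraction=0.3, edge_fraction=0.1, rng=rng)

    g1, t1 = build()
    g2, t2 = build()
    assert t1.equals(t2)
    for sp in g1:
        assert [c.seq for c in g1[sp]] == [c.seq for c in g2[sp]]


def test_emit_edge_loci_near_border(mining_fixture):
    truth = mining_fixture["truth"]
    genomes = mining_fixture["genomes"]
    edges = truth[truth["status"] == "edge"]
    assert len(edges) > 0
    for row in edges.itertuples():
        contig = next(c for c in genomes[row.species] if c.id == row.contig)
        border = min(row.start, len(contig.seq) - row.end)
        assert border < 30


def test_emit_gene_loci_translate_cleanly(mining_fixture):
    # re-derive each planted "gene" locus CDS from the genome and check ORF
    truth = mining_fixture["truth"]
    genomes = mining_fixture["genomes"]
    from Bio.Seq import Seq

    genes = truth[truth["status"] == "gene"]
    assert len(genes) > 0
    checked = 0
    for row in genes.itertuples():
        contig = next(c for c in genomes[row.species] if c.id == row.contig)
        dna = contig.seq[row.start:row.end]
        if row.strand == "-":
            dna = str(Seq(dna).reverse_complement())
        # splice out GT..AG introns greedily only for intronless loci here
        if row.family == "OR":
            assert dna[:3] == "ATG"
            assert dna[-3:] in STOP_CODONS
            prot = str(Seq(dna[:-3]).translate())
            assert "*" not in prot
            checked += 1
    assert checked > 0


def test_emit_counts_match_histories(mining_fixture):
    truth = mining_fixture["truth"]
    for fam, history in mining_fixture["histories"].items():
        for sp, n in history.tip_counts().items():
            got = len(truth[(truth["species"] == sp) & (truth["family"] == fam)])
            assert got == n


def test_emit_rejects_bad_fractions(mining_fixture, panel):
    with pytest.raises(ValueError):
        emit_genomes(mining_fixture["histories"], panel,
                     pseudo_fraction=0.8, truncated_fraction=0.4, seed=0)


def test_emit_rejects_empty_panel(mining_fixture):
    with pytest.raises(ValueError, match="panel"):
        emit_genomes(mining_fixture["histories"], [], seed=0)


# ------------------------------------------------------------------ traits

def test_lamellae_exact_when_noiseless(small_tree):
    counts = {sp: 100 for sp in small_tree.leaf_names()}
    table = simulate_lamellae(small_tree, counts, intercept=0.0, slope=0.1,
                              bm_sigma=0.0, seed=0)
    assert (table["lamellae"] == 10).all()


def test_lamellae_class_boundary(small_tree):
    for count, expected in [(20, "flat"), (30, "multilamellar")]:
        counts = {sp: count for sp in small_tree.leaf_names()}
        table = simulate_lamellae(small_tree, counts, intercept=0.0, slope=0.1,
                                  bm_sigma=0.0, seed=0)
        assert (table["epithelium"] == expected).all()


def test_lamellae_species_mismatch(small_tree):
    with pytest.raises(ValueError, match="mismatch"):
        simulate_lamellae(small_tree, {"nope": 1}, seed=0)


def test_trait_table_validation_catches_bad_class():
    import pandas as pd

    bad = pd.DataFrame(
        {"species": ["a"], "lamellae": [5], "epithelium": ["flat"]}
    )
    with pytest.raises(ValueError, match="epithelium"):
        validate_trait_table(bad)


# ------------------------------------------------------------------- panel

def test_random_cds_is_clean_orf():
    rng = np.random.default_rng(0)
    cds = random_cds(80, rng)
    assert cds[:3] == "ATG" and cds[-3:] == "TAA"
    assert all(cds[i:i + 3] not in STOP_CODONS for i in range(3, len(cds) - 3, 3))


def test_mutate_cds_preserves_orf():
    rng = np.random.default_rng(0)
    cds = random_cds(120, rng)
    mut = mutate_cds(cds, 0.15, rng)
    assert len(mut) == len(cds)
    assert mut[:3] == "ATG" and mut[-3:] == "TAA"
    assert all(mut[i:i + 3] not in STOP_CODONS for i in range(3, len(mut) - 3, 3))


def test_panel_round_trip():
    from olfevo.simulate import panel_from_records, panel_to_records

    panel = make_reference_panel(seed=1)
    back = panel_from_records(panel_to_records(panel))
    assert back == panel
    assert any(m.is_decoy for m in panel)
    families = {m.family for m in panel if not m.is_decoy}
    assert families == {"OR", "TAAR", "OlfC", "ORA"}
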