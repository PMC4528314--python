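"""Relationship matrices: tabular A vs a recursive coancestry oracle, G identities."""

import numpy as np
import pandas as pd
import pytest

from crossblup.genio import DataError, GenotypeMatrix, PedigreeTable
from crossblup.kinship import (
    build_A,
    build_G_across,
    build_G_vanraden,
    f1_line_freqs,
    mean_relatedness_split,
    read_matrix,
    write_matrix,
)


def coancestry_oracle(ped_df):
    """Malecot kinship by direct recursion over ancestors, independent of the
    tabular method; additive relationship a_ij = 2 * f_ij."""
    sire = dict(zip(ped_df["animal"], ped_df["sire"]))
    dam = dict(zip(ped_df["animal"], ped_df["dam"]))
    order = {a: i for i, a in enumerate(ped_df["animal"])}
    cache = {}

    def f(x, y):
        if x == "0" or y == "0":
            return 0.0
        key = (x, y) if order[x] <= order[y] else (y, x)
        if key in cache:
            return cache[key]
        if x == y:
            val = 0.5 * (1.0 + f(sire[x], dam[x]))
        else:
            # recurse on the younger individual's parents
            a, b = (x, y) if order[x] > order[y] else (y, x)
            val = 0.5 * (f(sire[a], b) + f(dam[a], b))
        cache[key] = val
        return val

    animals = list(ped_df["animal"])
    n = len(animals)
    A = np.empty((n, n))
    for i, x in enumerate(animals):
        for j, y in enumerate(animals):
            A[i, j] = 2.0 * f(x, y)
    return A


def random_pedigree(n, rng):
    """Random valid pedigree of n animals, parents always older."""
    rows = []
    for i in range(n):
        if i < 2 or rng.random() < 0.3:
            s = d = "0"
        else:
            s, d = rng.choice(i, size=2, replace=False)
            s, d = f"p{s}", f"p{d}"
        rows.append({"animal": f"p{i}", "sire": s, "dam": d, "line": "L1"})
    return pd.DataFrame(rows)


def test_A_textbook_cases(tiny_pedigree_df):
    A = build_A(PedigreeTable(tiny_pedigree_df))
    i = {a: k for k, a in enumerate(A.animal_ids)}
    # offspring-parent 0.5, full sibs 0.5
    assert A.values[i["A"], i["S"]] == pytest.approx(0.5)
    assert A.values[i["A"], i["B"]] == pytest.approx(0.5)
    # C is the offspring of full sibs A x B: F = 0.25, diagonal 1.25
    assert A.values[i["C"], i["C"]] == pytest.approx(1.25)
    # founders noninbred
    assert A.values[i["S"], i["S"]] == pytest.approx(1.0)


@pytest.mark.parametrize("seed", range(12))
def test_A_matches_recursive_oracle(seed):
    rng = np.random.default_rng(seed)
    df = random_pedigree(int(rng.integers(3, 9)), rng)
    A = build_A(PedigreeTable(df))
    # PedigreeTable may reorder; realign oracle to its order
    df2 = PedigreeTable(df).df
    expected = coancestry_oracle(df2)
    np.testing.assert_allclose(A.values, expected, atol=1e-12)


def test_A_subset_keeps_ancestral_recursion(tiny_pedigree_df):
    full = build_A(PedigreeTable(tiny_pedigree_df))
    sub = build_A(PedigreeTable(tiny_pedigree_df), subset=["C", "A"])
    i = {a: k for k, a in enumerate(full.animal_ids)}
    assert sub.values[0, 0] == pytest.approx(full.values[i["C"], i["C"]])
    assert sub.values[0, 1] == pytest.approx(full.values[i["C"], i["A"]])
    with pytest.raises(DataError):
        build_A(PedigreeTable(tiny_pedigree_df), subset=["nope"])


def test_G_hand_example():
    # dosages [0,2] and [2,0]; observed p = (0.5, 0.5); Z rows (-1,1),(1,-1);
    # denominator 2*sum(pq) = 1; G = [[2,-2],[-2,2]]
    g = GenotypeMatrix(dosages=[[0, 2], [2, 0]], animal_ids=["x", "y"], snp_ids=["s1", "s2"])
    G = build_G_vanraden(g)
    np.testing.assert_allclose(G.values, [[2, -2], [-2, 2]], atol=1e-12)


def test_G_row_sums_zero_under_observed_centering(rng):
    dos = rng.binomial(2, rng.uniform(0.1, 0.5, 300), size=(40, 300)).astype(float)
    G = build_G_vanraden(GenotypeMatrix(
        dosages=dos, animal_ids=[f"a{i}" for i in range(40)],
        snp_ids=[f"s{j}" for j in range(300)]))
    np.testing.assert_allclose(G.values.sum(axis=1), 0.0, atol=1e-8)


def test_G_allele_flip_invariance(rng):
    dos = rng.binomial(2, rng.uniform(0.1, 0.5, 200), size=(30, 200)).astype(float)
    ids = [f"a{i}" for i in range(30)]
    snps = [f"s{j}" for j in range(200)]
    G1 = build_G_vanraden(GenotypeMatrix(dosages=dos, animal_ids=ids, snp_ids=snps))
    flipped = dos.copy()
    flip = rng.random(200) < 0.5
    flipped[:, flip] = 2.0 - flipped[:, flip]
    G2 = build_G_vanraden(GenotypeMatrix(dosages=flipped, animal_ids=ids, snp_ids=snps))
    np.testing.assert_allclose(G1.values, G2.values, atol=1e-10)


def test_G_duplicate_animals_copy_symmetry(rng):
    dos = rng.binomial(2, 0.4, size=(5, 100)).astype(float)
    dos[4] = dos[0]  # duplicate genotype row
    G = build_G_vanraden(GenotypeMatrix(
        dosages=dos, animal_ids=["a", "b", "c", "d", "a_copy"],
        snp_ids=[f"s{j}" for j in range(100)]))
    np.testing.assert_allclose(G.values[0], G.values[4], atol=1e-12)
    assert G.values[0, 0] == pytest.approx(G.values[4, 4])


def test_G_monomorphic_errors():
    g = GenotypeMatrix(dosages=np.zeros((3, 4)), animal_ids=["a", "b", "c"],
                       snp_ids=list("wxyz"))
    with pytest.raises(DataError, match="monomorphic"):
        build_G_vanraden(g)


def test_G_mean_diagonal_near_one(rng):
    # Hardy-Weinberg data with observed-frequency centering: E[diag] -> 1
    m = 4000
    dos = rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(200, m)).astype(float)
    G = build_G_vanraden(GenotypeMatrix(
        dosages=dos, animal_ids=[f"a{i}" for i in range(200)],
        snp_ids=[f"s{j}" for j in range(m)]))
    assert np.mean(np.diag(G.values)) == pytest.approx(1.0, abs=0.05)


def test_G_across_single_line_collapses(rng):
    dos = rng.binomial(2, rng.uniform(0.2, 0.5, 150), size=(20, 150)).astype(float)
    gm = GenotypeMatrix(dosages=dos, animal_ids=[f"a{i}" for i in range(20)],
                        snp_ids=[f"s{j}" for j in range(150)], lines=["L1"] * 20)
    np.testing.assert_allclose(
        build_G_across(gm).values, build_G_vanraden(gm).values, atol=1e-12
    )


def test_G_across_blockwise_preserves_within_line_blocks(rng):
    dos = np.vstack([
        rng.binomial(2, rng.uniform(0.1, 0.4, 200), size=(15, 200)),
        rng.binomial(2, rng.uniform(0.3, 0.5, 200), size=(12, 200)),
    ]).astype(float)
    lines = ["L1"] * 15 + ["L2"] * 12
    ids = [f"a{i}" for i in range(27)]
    snps = [f"s{j}" for j in range(200)]
    gm = GenotypeMatrix(dosages=dos, animal_ids=ids, snp_ids=snps, lines=lines)
    G = build_G_across(gm, denominator="blockwise")
    for lab, sl in (("L1", slice(0, 15)), ("L2", slice(15, 27))):
        own = build_G_vanraden(gm.subset(animals=np.array(ids)[sl]))
        np.testing.assert_allclose(G.values[sl, sl], own.values, atol=1e-10)
    # cross blocks finite and the whole matrix symmetric
    assert np.isfinite(G.values).all()
    np.testing.assert_allclose(G.values, G.values.T, atol=1e-12)


def test_G_across_f1_parental_mean_freqs(rng):
    dos = np.vstack([
        rng.binomial(2, 0.2, size=(10, 100)),
        rng.binomial(2, 0.6, size=(10, 100)),
        rng.binomial(2, 0.4, size=(5, 100)),
    ]).astype(float)
    lines = ["L1"] * 10 + ["L2"] * 10 + ["F1"] * 5
    gm = GenotypeMatrix(dosages=dos, animal_ids=[f"a{i}" for i in range(25)],
                        snp_ids=[f"s{j}" for j in range(100)], lines=lines)
    pf1 = f1_line_freqs(gm, "F1", ("L1", "L2"), min_f1=30)  # < 30 F1 -> parental mean
    np.testing.assert_allclose(
        pf1, 0.5 * (dos[:10].mean(0) / 2 + dos[10:20].mean(0) / 2), atol=1e-12
    )
    G = build_G_across(gm, line_freqs={"F1": pf1})
    assert np.isfinite(G.values).all()
    np.testing.assert_allclose(G.values, G.values.T, atol=1e-10)


def test_A_G_entrywise_correlation(small_working_set):
    ws = small_working_set
    ids = [a for a in ws.genotypes.animal_ids if ws.genotypes.line_of(a) == "L1"]
    A = ws.full_A().subset(ids)
    G = build_G_vanraden(ws.genotypes.subset(animals=ids))
    iu = np.triu_indices(len(ids), k=1)
    r = np.corrcoef(A.values[iu], G.values[iu])[0, 1]
    assert r > 0.8


def test_mean_relatedness_split():
    vals = np.eye(11)
    ids = [f"t{i}" for i in range(10)] + ["v"]
    # training scores 0.1 .. 1.0 against the single validation animal
    vals[:10, 10] = vals[10, :10] = np.arange(0.1, 1.05, 0.1)
    from crossblup.kinship import RelationshipMatrix
    K = RelationshipMatrix(values=vals, animal_ids=ids, kind="pedigree")
    most, least, scores = mean_relatedness_split(K, ids[:10], ["v"])
    assert set(most) == {f"t{i}" for i in range(5, 10)}  # top five scores
    assert set(least) == {f"t{i}" for i in range(5)}
    # two-point ranking
    most2, least2, _ = mean_relatedness_split(K, ["t9", "t0"], ["v"])
    assert (most2, least2) == (["t9"], ["t0"])
    # ties: stable ID order decides
    K2 = RelationshipMatrix(values=np.full((5, 5), 0.25) + 0.75 * np.eye(5),
                            animal_ids=["a", "b", "c", "d", "v"], kind="pedigree")
    m3, l3, _ = mean_relatedness_split(K2, ["a", "b", "c", "d"], ["v"])
    assert m3 == ["a", "b"] and l3 == ["c", "d"]
    with pytest.raises(DataError, match="overlap"):
        mean_relatedness_split(K, ["t1"], ["t1"])


def test_matrix_text_round_trip(tmp_path, rng):
    dos = rng.binomial(2, 0.4, size=(6, 60)).astype(float)
    G = build_G_vanraden(GenotypeMatrix(
        dosages=dos, animal_ids=[f"a{i}" for i in range(6)],
        snp_ids=[f"s{j}" for j in range(60)]))
    p = tmp_path / "G.csv"
    write_matrix(G, p)
    back = read_matrix(p)
    np.testing.assert_allclose(back.values, G.values, atol=1e-9)
    assert list(back.animal_ids) == list(G.animal_ids)
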