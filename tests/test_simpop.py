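"""Synthetic population generator: sampling oracles and determinism."""

import numpy as np
import pandas as pd
import pytest

from crossblup.genio import DataError
from crossblup.simpop import (
    PopulationSpec,
    assign_effects_and_phenotypes,
    drift_frequencies,
    drift_lines,
    make_f1,
    simulate_dataset,
    simulate_founders,
)


def test_spec_validation():
    with pytest.raises(DataError):
        PopulationSpec(founder_maf_range=(0.2, 0.7)).validate()
    with pytest.raises(DataError):
        PopulationSpec(n_qtl=10, n_snps=5).validate()
    with pytest.raises(DataError):
        PopulationSpec(rho_pbcb=1.5).validate()
    with pytest.raises(DataError):
        PopulationSpec(effective_size=1).validate()


def test_founders_degenerate_maf_interval():
    spec = PopulationSpec(n_founders=50, n_snps=40, n_qtl=10,
                          founder_maf_range=(0.5, 0.5), seed=1)
    _, p0 = simulate_founders(spec)
    np.testing.assert_allclose(p0, 0.5)


def test_founders_deterministic():
    spec = PopulationSpec(n_founders=30, n_snps=50, n_qtl=10, seed=7)
    g1, p1 = simulate_founders(spec)
    g2, p2 = simulate_founders(spec)
    np.testing.assert_array_equal(g1.dosages, g2.dosages)
    np.testing.assert_array_equal(p1, p2)


def test_founder_heterozygosity_matches_binomial(rng):
    # at p = 0.3 expected heterozygosity is 2*0.3*0.7 = 0.42
    spec = PopulationSpec(n_founders=2000, n_snps=1000, n_qtl=10,
                          founder_maf_range=(0.3, 0.3), seed=2)
    g, _ = simulate_founders(spec)
    het = float(np.mean(g.dosages == 1))
    se = np.sqrt(0.42 * 0.58 / g.dosages.size)
    assert abs(het - 0.42) < 3 * se


def test_drift_zero_generations_is_identity(rng):
    p0 = rng.uniform(0.1, 0.5, 100)
    freqs, fst = drift_frequencies(p0, 0, 50, 2, rng)
    for p in freqs:
        np.testing.assert_array_equal(p, p0)
    assert fst == pytest.approx(0.0)


def test_drift_fst_matches_wright_fisher(rng):
    """Realized Fst across many replicate SNP sets matches 1-(1-1/2Ne)^t."""
    ne, t = 50, 10
    expected = 1 - (1 - 1 / (2 * ne)) ** t
    fsts = []
    for _ in range(250):
        p0 = rng.uniform(0.2, 0.5, 60)
        _, fst = drift_frequencies(p0, t, ne, 2, rng)
        fsts.append(fst)
    fsts = np.array(fsts)
    se = fsts.std(ddof=1) / np.sqrt(len(fsts))
    assert abs(fsts.mean() - expected) < 3 * se


def test_drift_is_unbiased(rng):
    """Mean final frequency over replicates equals the founder frequency."""
    p0 = np.full(400, 0.3)
    finals = []
    for _ in range(60):
        freqs, _ = drift_frequencies(p0, 8, 40, 1, rng)
        finals.append(freqs[0])
    mean_p = np.mean(finals)
    n_draws = 60 * 400
    se = np.sqrt(0.3 * 0.7 / (2 * 40)) * np.sqrt(8) / np.sqrt(n_draws)  # rough drift SE
    assert abs(mean_p - 0.3) < 5 * se


def test_fst_monotone_in_generations():
    means = []
    for t in (2, 8, 20):
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            p0 = rng.uniform(0.2, 0.5, 150)
            _, fst = drift_frequencies(p0, t, 60, 2, rng)
            vals.append(fst)
        means.append(np.mean(vals))
    assert means[0] < means[1] < means[2]


def _parents(dosage_value, n, n_snps, lab):
    from crossblup.genio import GenotypeMatrix
    return GenotypeMatrix(
        dosages=np.full((n, n_snps), float(dosage_value)),
        animal_ids=[f"{lab}{i}" for i in range(n)],
        snp_ids=[f"s{j}" for j in range(n_snps)],
        lines=[lab] * n,
    )


def test_f1_forced_heterozygosity(rng):
    a = _parents(2, 5, 20, "A")
    b = _parents(0, 5, 20, "B")
    f1, ped = make_f1(a, b, 30, rng=rng)
    np.testing.assert_array_equal(f1.dosages, 1.0)
    assert ped["sire"].str.startswith("A").all()
    assert ped["dam"].str.startswith("B").all()
    assert (ped["line"] == "F1").all()


def test_f1_allele_frequency_oracle(rng):
    # F1 frequency per SNP ~ (p_A + p_B)/2
    pa, pb = 0.2, 0.6
    from crossblup.genio import GenotypeMatrix
    a = GenotypeMatrix(dosages=rng.binomial(2, pa, (200, 300)).astype(float),
                       animal_ids=[f"A{i}" for i in range(200)],
                       snp_ids=[f"s{j}" for j in range(300)], lines=["A"] * 200)
    b = GenotypeMatrix(dosages=rng.binomial(2, pb, (200, 300)).astype(float),
                       animal_ids=[f"B{i}" for i in range(200)],
                       snp_ids=[f"s{j}" for j in range(300)], lines=["B"] * 200)
    f1, _ = make_f1(a, b, 400, rng=rng)
    freq = f1.allele_freq().mean()
    se = np.sqrt(0.5 * 0.5 / (2 * 400 * 300)) * 3  # crude but conservative scale
    assert abs(freq - (pa + pb) / 2) < 0.01 + se


def test_f1_empty_parents_error(rng):
    a = _parents(1, 3, 5, "A")
    empty = a.subset(animals=[])
    with pytest.raises(DataError, match="empty"):
        make_f1(empty, a, 5, rng=rng)


def test_effects_rho_one_degenerate(rng):
    spec = PopulationSpec(n_snps=200, n_qtl=60, rho_pbcb=1.0,
                          line_means={"A": 0.0}, lines=("A",), n_f1=0, seed=3)
    g = {"A": _parents(1, 2, 200, "A")}
    # identical effect vectors up to scaling: correlation exactly 1
    from crossblup.simpop import SimTruth
    rng2 = np.random.default_rng(0)
    dos = rng2.binomial(2, rng2.uniform(0.2, 0.5, 200), (500, 200)).astype(float)
    from crossblup.genio import GenotypeMatrix
    gm = GenotypeMatrix(dosages=dos, animal_ids=[f"A{i}" for i in range(500)],
                        snp_ids=[f"s{j}" for j in range(200)], lines=["A"] * 500)
    truth, _ = assign_effects_and_phenotypes({"A": gm}, spec, rng=rng2)
    r = np.corrcoef(truth.qtl_effects_pb, truth.qtl_effects_cb)[0, 1]
    assert r == pytest.approx(1.0, abs=1e-12)


def test_effects_correlation_oracle():
    # sample correlation of (u_pb, u_cb) pairs within 3 SEs of rho
    rho, n_qtl = 0.9, 500
    spec = PopulationSpec(n_snps=1000, n_qtl=n_qtl, rho_pbcb=rho,
                          lines=("A",), n_f1=0, line_means={"A": 0.0}, seed=5)
    rng = np.random.default_rng(9)
    from crossblup.genio import GenotypeMatrix
    dos = rng.binomial(2, rng.uniform(0.2, 0.5, 1000), (300, 1000)).astype(float)
    gm = GenotypeMatrix(dosages=dos, animal_ids=[f"A{i}" for i in range(300)],
                        snp_ids=[f"s{j}" for j in range(1000)], lines=["A"] * 300)
    truth, _ = assign_effects_and_phenotypes({"A": gm}, spec, rng=rng)
    r = np.corrcoef(truth.qtl_effects_pb, truth.qtl_effects_cb)[0, 1]
    se = (1 - rho**2) / np.sqrt(n_qtl - 3)  # Fisher-z scale approximation
    assert abs(r - rho) < 3 * se + 0.01


def test_phenotype_regression_on_tbv_near_one(small_data):
    ph = small_data.phenotypes
    x = ph["tbv"].to_numpy()
    y = ph["phenotype"].to_numpy()
    # within-line regression (line means shift both)
    slopes = []
    for _, grp in ph.groupby("line"):
        xx = grp["tbv"] - grp["tbv"].mean()
        yy = grp["phenotype"] - grp["phenotype"].mean()
        slopes.append(float((xx * yy).sum() / (xx * xx).sum()))
    assert np.mean(slopes) == pytest.approx(1.0, abs=0.1)


def test_variance_bookkeeping(small_data):
    """Realized var(TBV)/var(record) matches the heritability accounting.

    The emitted phenotype is a mean of n_parities repeated records, so on
    that scale the additive share is h2 / (h2 + (1 - h2)/k); with k = 1 this
    reduces to h2 of the unit single-record variance.
    """
    h2, k = small_data.spec.h2, small_data.spec.n_parities
    expected = h2 / (h2 + (1 - h2) / k)
    for _, grp in small_data.phenotypes.groupby("line"):
        ratio = grp["tbv"].var() / grp["phenotype"].var()
        assert ratio == pytest.approx(expected, abs=0.08)


def test_h2_zero_rejected():
    spec = PopulationSpec(h2=0.0, lines=("A",), n_f1=0, line_means={"A": 0.0},
                          n_snps=50, n_qtl=10)
    with pytest.raises(DataError, match="h2"):
        assign_effects_and_phenotypes({"A": _parents(1, 5, 50, "A")}, spec,
                                      rng=np.random.default_rng(0))


def test_tbv_reproducible_from_genotypes_and_effects(small_data):
    """TBV equals the dot product of QTL dosages with the effect vector."""
    data = small_data
    gm = data.genotypes
    qtl_pos = [list(gm.snp_ids).index(q) for q in data.truth.qtl_ids]
    pb = [a for a in gm.animal_ids if gm.line_of(a) != "F1"][:20]
    sub = gm.subset(animals=pb)
    dos = sub.dosages[:, qtl_pos]
    mask = np.isnan(dos)
    # undo injected missingness using the complete-truth TBVs only where intact
    intact = ~mask.any(axis=1)
    got = dos[intact] @ data.truth.qtl_effects_pb
    want = data.truth.true_bv_pb[np.array(pb)[intact]].to_numpy()
    np.testing.assert_allclose(got, want, atol=1e-10)


def test_dataset_determinism_and_reliability_range(small_data):
    spec = small_data.spec
    again = simulate_dataset(spec)
    np.testing.assert_array_equal(
        small_data.genotypes.dosages, again.genotypes.dosages
    )
    pd.testing.assert_frame_equal(small_data.traits.df, again.traits.df)
    r2 = small_data.traits.df["r2"]
    assert ((r2 > 0) & (r2 <= 0.99)).all()


def test_pedigree_orders_parents_first(small_data):
    ped = small_data.pedigree
    seen = set()
    for _, row in ped.df.iterrows():
        for p in (row["sire"], row["dam"]):
            assert p == "0" or p in seen
        seen.add(row["animal"])


def test_drift_lines_wrapper(rng):
    spec = PopulationSpec(n_founders=100, n_snps=200, n_qtl=20, seed=4)
    founders, _ = simulate_founders(spec)
    freqs, mats, fst = drift_lines(founders, 5, 50, 2, 30, rng=rng)
    assert set(freqs) == {"L1", "L2"}
    assert mats["L1"].n_animals == 30
    assert 0 <= fst < 1
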