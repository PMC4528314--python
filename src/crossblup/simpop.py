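"""Synthetic multi-line pig populations for exercising the prediction pipeline.

The generator emulates the data structure the analysis assumes: two purebred
nucleus lines diverged by pure drift from a common founder population, plus
an F1 cross between them.  Per line, allele frequencies evolve by
Wright-Fisher binomial resampling of 2*Ne gametes per generation; unrelated
base animals are then drawn Hardy-Weinberg at the drifted frequencies and
two generations of random matings (Mendelian gene dropping, no linkage)
create the genotyped cohort, so the pedigree carries real family structure.
F1 animals receive one gamete from a purebred sire of one line and one from
a dam of the other.

The trait is additive: a subset of SNPs are QTL whose purebred- and
crossbred-context allele-substitution effects are drawn from a zero-mean
bivariate normal with correlation rho_pbcb, the standard reduction of the
two-trait purebred/crossbred model.  True breeding values are rescaled so
that the additive variance matches h2 of a unit total variance, and
phenotype = line mean + TBV + N(0, 1 - h2).  Pseudo-EBVs and reliabilities
mirror a routine pedigree evaluation: the package's own PED-BLUP (line fixed
effect, true variance components) is run on the simulated phenotypes, with
per-animal reliability r2 = 1 - PEV / sigma2_a.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .genio import DataError, GenotypeMatrix, PedigreeTable, TraitTable, UNKNOWN_PARENT
from .kinship import build_A
from .varcomp import design_matrix, solve_blup

N_AUTOSOMES = 18  # pig karyotype; labels only, SNPs assort independently


@dataclass
class PopulationSpec:
    """Parameters of the simulated breeding structure.

    Defaults are desk-scale: two purebred lines of 1,200 genotyped sows and
    an F1 cross of 290, genotyped at 5,000 SNPs of which 500 are QTL, with
    lines drifted for 30 generations at Ne = 100 (expected Fst ~ 0.14).
    """

    n_founders: int = 400
    n_per_line: int = 1200
    n_f1: int = 290
    n_snps: int = 5000
    n_qtl: int = 500
    founder_maf_range: tuple = (0.1, 0.5)
    drift_generations: int = 30
    effective_size: int = 100
    lines: tuple = ("L1", "L2")
    f1_line: str = "F1"
    line_means: dict = field(default_factory=lambda: {"L1": 0.0, "L2": 0.5, "F1": 0.25})
    h2: float = 0.3
    rho_pbcb: float = 0.6
    n_parities: int = 4
    n_base_per_line: int = 200
    f1_n_sires: int = 76
    f1_n_dams: int = 170
    gap_generations: int = 2
    missing_rate: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.founder_maf_range
        if not (0 <= lo <= hi <= 0.5):
            raise DataError(f"founder_maf_range must lie in [0, 0.5], got {self.founder_maf_range}")
        if self.n_qtl > self.n_snps:
            raise DataError("n_qtl must not exceed n_snps")
        if not 0 <= self.h2 <= 1:
            raise DataError("h2 must be in [0, 1]")
        if abs(self.rho_pbcb) > 1:
            raise DataError("|rho_pbcb| must be <= 1")
        if self.drift_generations < 0:
            raise DataError("drift_generations must be >= 0")
        if self.effective_size < 2:
            raise DataError("effective_size must be >= 2")
        for lab in (*self.lines, self.f1_line):
            if self.n_f1 > 0 or lab != self.f1_line:
                if lab not in self.line_means:
                    raise DataError(f"line_means missing entry for {lab!r}")
        if not 0 <= self.missing_rate < 1:
            raise DataError("missing_rate must be in [0, 1)")
        if self.n_parities < 1:
            raise DataError("n_parities must be >= 1")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["founder_maf_range"] = list(self.founder_maf_range)
        d["lines"] = list(self.lines)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PopulationSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["founder_maf_range"] = tuple(d.get("founder_maf_range", (0.1, 0.5)))
        d["lines"] = tuple(d.get("lines", ("L1", "L2")))
        spec = cls(**d)
        spec.validate()
        return spec


@dataclass
class SimTruth:
    """Ground truth for parameter-recovery tests."""

    true_bv_pb: pd.Series          # purebred-context TBV, every animal
    true_bv_cb: pd.Series          # crossbred-context TBV, every animal
    qtl_ids: np.ndarray
    qtl_effects_pb: np.ndarray     # scaled allele-substitution effects
    qtl_effects_cb: np.ndarray
    line_freqs: dict               # line -> per-SNP drifted frequency
    founder_freqs: np.ndarray
    realized_fst: float


@dataclass
class SimulatedData:
    spec: PopulationSpec
    genotypes: GenotypeMatrix      # genotyped cohort (+F1), missing injected
    pedigree: PedigreeTable        # full pedigree including base animals
    traits: TraitTable             # pseudo-EBV and reliability per genotyped animal
    phenotypes: pd.DataFrame       # animal, line, phenotype, tbv (all animals)
    truth: SimTruth
    line_effects: dict             # fixed line-effect estimates from PED-BLUP


# ---------------------------------------------------------------------------
# elementary operations


def _snp_metadata(n_snps: int):
    snp_ids = np.array([f"snp{j + 1:05d}" for j in range(n_snps)], dtype=object)
    chrom = np.array([str(j % N_AUTOSOMES + 1) for j in range(n_snps)], dtype=object)
    pos = np.array([(j // N_AUTOSOMES + 1) * 1000 for j in range(n_snps)], dtype=int)
    return snp_ids, chrom, pos


def simulate_founders(spec: PopulationSpec, rng=None):
    """Founder population: frequencies uniform on the MAF range, HWE genotypes."""
    spec.validate()
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    lo, hi = spec.founder_maf_range
    p0 = rng.uniform(lo, hi, spec.n_snps)
    p0 = np.minimum(p0, 1.0 - p0)  # fold to the minor allele
    dosages = rng.binomial(2, p0, size=(spec.n_founders, spec.n_snps)).astype(float)
    snp_ids, chrom, pos = _snp_metadata(spec.n_snps)
    gm = GenotypeMatrix(
        dosages=dosages,
        animal_ids=np.array([f"F0_{i + 1:05d}" for i in range(spec.n_founders)], dtype=object),
        snp_ids=snp_ids,
        lines=np.full(spec.n_founders, "founder", dtype=object),
        chrom=chrom,
        pos=pos,
    )
    return gm, p0


def drift_frequencies(p0, generations: int, effective_size: int, n_lines: int, rng):
    """Per-line Wright-Fisher drift of allele frequencies.

    Each generation resamples 2*Ne gametes binomially.  Realized Fst is
    measured against the known founder frequencies,
    mean_l mean_i (p_li - p0i)^2 / mean_i (p0i * q0i), whose expectation is
    1 - (1 - 1/(2*Ne))^t under pure drift.
    """
    if generations < 0:
        raise DataError("generations must be >= 0")
    if effective_size < 2:
        raise DataError("effective_size must be >= 2")
    p0 = np.asarray(p0, dtype=float)
    freqs = []
    for _ in range(n_lines):
        p = p0.copy()
        for _ in range(generations):
            p = rng.binomial(2 * effective_size, p) / (2.0 * effective_size)
        freqs.append(p)
    denom = np.mean(p0 * (1.0 - p0))
    if denom > 0:
        fst = float(np.mean([(p - p0) ** 2 for p in freqs]) / denom)
    else:
        fst = 0.0
    return freqs, fst


def drift_lines(founders: GenotypeMatrix, generations: int, effective_size: int,
                n_lines: int, n_per_line: int, seed=None, rng=None, line_labels=None):
    """Drift founder frequencies into lines and draw HWE line genotypes."""
    rng = np.random.default_rng(seed) if rng is None else rng
    p0 = founders.allele_freq()
    freqs, fst = drift_frequencies(p0, generations, effective_size, n_lines, rng)
    labels = line_labels or [f"L{k + 1}" for k in range(n_lines)]
    mats = {}
    for lab, p in zip(labels, freqs):
        dos = rng.binomial(2, p, size=(n_per_line, founders.n_snps)).astype(float)
        mats[lab] = GenotypeMatrix(
            dosages=dos,
            animal_ids=np.array([f"{lab}_B{i + 1:05d}" for i in range(n_per_line)], dtype=object),
            snp_ids=founders.snp_ids,
            lines=np.full(n_per_line, lab, dtype=object),
            chrom=founders.chrom,
            pos=founders.pos,
        )
    return dict(zip(labels, freqs)), mats, fst


def _mate(parent_dosages_s, parent_dosages_d, sire_idx, dam_idx, rng):
    """Mendelian gene dropping without linkage: gamete_j ~ Bernoulli(d_j/2)."""
    ps = parent_dosages_s[sire_idx]
    pd_ = parent_dosages_d[dam_idx]
    gam_s = rng.binomial(1, ps / 2.0)
    gam_d = rng.binomial(1, pd_ / 2.0)
    return (gam_s + gam_d).astype(float)


def make_f1(line_a_parents: GenotypeMatrix, line_b_parents: GenotypeMatrix,
            n_offspring: int, seed=None, rng=None, n_sires=None, n_dams=None,
            f1_line: str = "F1"):
    """F1 cross: sires from line A, dams from line B, one gamete from each.

    Returns the F1 genotype matrix and the pedigree rows (animal, sire, dam,
    line) recording the matings.
    """
    if line_a_parents.n_animals == 0 or line_b_parents.n_animals == 0:
        raise DataError("empty parent set for the F1 cross")
    if not np.array_equal(line_a_parents.snp_ids, line_b_parents.snp_ids):
        raise DataError("parent matrices must share the SNP set")
    rng = np.random.default_rng(seed) if rng is None else rng
    n_sires = min(n_sires or line_a_parents.n_animals, line_a_parents.n_animals)
    n_dams = min(n_dams or line_b_parents.n_animals, line_b_parents.n_animals)
    sire_pool = rng.choice(line_a_parents.n_animals, size=n_sires, replace=False)
    dam_pool = rng.choice(line_b_parents.n_animals, size=n_dams, replace=False)
    sires = rng.choice(sire_pool, size=n_offspring, replace=True)
    dams = rng.choice(dam_pool, size=n_offspring, replace=True)
    dos = np.empty((n_offspring, line_a_parents.n_snps))
    for i in range(n_offspring):
        dos[i] = _mate(line_a_parents.dosages, line_b_parents.dosages, sires[i], dams[i], rng)
    ids = np.array([f"{f1_line}_{i + 1:05d}" for i in range(n_offspring)], dtype=object)
    gm = GenotypeMatrix(
        dosages=dos,
        animal_ids=ids,
        snp_ids=line_a_parents.snp_ids,
        lines=np.full(n_offspring, f1_line, dtype=object),
        chrom=line_a_parents.chrom,
        pos=line_a_parents.pos,
    )
    ped_rows = pd.DataFrame(
        {
            "animal": ids,
            "sire": line_a_parents.animal_ids[sires],
            "dam": line_b_parents.animal_ids[dams],
            "line": f1_line,
        }
    )
    return gm, ped_rows


def assign_effects_and_phenotypes(genotypes_by_line: dict, spec: PopulationSpec, rng=None):
    """Draw correlated QTL effects, compute TBVs and phenotypes.

    QTL effect pairs (u_pb, u_cb) come from a zero-mean bivariate normal
    with correlation rho_pbcb; purebred animals express u_pb, F1 animals
    u_cb.  Each context's TBVs are rescaled so the within-line additive
    variance is h2 of a unit single-record variance; the emitted phenotype
    is the mean of n_parities repeated records, line mean + TBV +
    N(0, (1 - h2) / n_parities), mirroring multi-parity sow data where
    repeated records are absorbed into the record's information content.
    """
    spec.validate()
    if spec.h2 == 0:
        raise DataError("h2 = 0 leaves no genetic signal to scale")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    any_gm = next(iter(genotypes_by_line.values()))
    qtl_idx = np.sort(rng.choice(any_gm.n_snps, size=spec.n_qtl, replace=False))
    z1 = rng.standard_normal(spec.n_qtl)
    z2 = rng.standard_normal(spec.n_qtl)
    rho = spec.rho_pbcb
    u_pb = z1
    u_cb = rho * z1 + np.sqrt(max(0.0, 1.0 - rho**2)) * z2

    raw_pb, raw_cb, rows = {}, {}, []
    for lab, gm in genotypes_by_line.items():
        Xq = gm.dosages[:, qtl_idx]
        if np.isnan(Xq).any():
            raise DataError("phenotype assignment requires complete genotypes")
        raw_pb[lab] = Xq @ u_pb
        raw_cb[lab] = Xq @ u_cb

    def _pooled_within_line_var(vals_by_line, labs):
        devs = [vals_by_line[lab] - vals_by_line[lab].mean() for lab in labs if len(vals_by_line[lab])]
        pooled = np.concatenate(devs)
        return float(pooled.var())

    pb_labels = [lab for lab in genotypes_by_line if lab != spec.f1_line]
    cb_labels = [lab for lab in genotypes_by_line if lab == spec.f1_line]
    var_pb = _pooled_within_line_var(raw_pb, pb_labels)
    var_cb = _pooled_within_line_var(raw_cb, cb_labels) if cb_labels else var_pb
    if var_pb <= 0 or var_cb <= 0:
        raise DataError("degenerate genetic variance; check QTL frequencies")
    s_pb = np.sqrt(spec.h2 / var_pb)
    s_cb = np.sqrt(spec.h2 / var_cb)

    sigma_e = np.sqrt(max(0.0, 1.0 - spec.h2) / spec.n_parities)
    tbv_pb_all, tbv_cb_all = {}, {}
    for lab, gm in genotypes_by_line.items():
        tbv_pb = raw_pb[lab] * s_pb
        tbv_cb = raw_cb[lab] * s_cb
        expressed = tbv_cb if lab == spec.f1_line else tbv_pb
        noise = rng.normal(0.0, sigma_e, gm.n_animals)
        mean = spec.line_means.get(lab, 0.0)
        for i, a in enumerate(gm.animal_ids):
            tbv_pb_all[a] = tbv_pb[i]
            tbv_cb_all[a] = tbv_cb[i]
            rows.append((a, lab, mean + expressed[i] + noise[i], expressed[i]))
    phen = pd.DataFrame(rows, columns=["animal", "line", "phenotype", "tbv"])
    truth = SimTruth(
        true_bv_pb=pd.Series(tbv_pb_all),
        true_bv_cb=pd.Series(tbv_cb_all),
        qtl_ids=any_gm.snp_ids[qtl_idx],
        qtl_effects_pb=u_pb * s_pb,
        qtl_effects_cb=u_cb * s_cb,
        line_freqs={},
        founder_freqs=np.array([]),
        realized_fst=np.nan,
    )
    return truth, phen


def pedblup_ebvs(phenotypes: pd.DataFrame, ped: PedigreeTable, h2: float,
                 n_parities: int = 1):
    """Pseudo-EBVs from this package's own PED-BLUP on simulated phenotypes.

    Fits y = line + a with var(a) = A*h2 on the single-record variance
    scale; each phenotype is a mean of ``n_parities`` records, entering with
    residual variance (1-h2)/n_parities via a record weight.  Reliability
    per animal is 1 - PEV / (A_ii * sigma2_a).  As in a routine evaluation,
    EBVs and reliabilities are published for every pedigree animal,
    phenotyped or not (unphenotyped connectors receive relative-derived
    EBVs, which downstream parent-adjusted deregression needs).  Returns a
    TraitTable and the estimated line effects (reference line 0).
    """
    A = build_A(ped)
    phen = phenotypes.set_index("animal").loc[
        [a for a in A.animal_ids if a in set(phenotypes["animal"])]
    ]
    record_ids = list(phen.index)
    X, levels = design_matrix(phen["line"].to_numpy())
    sol = solve_blup(
        y=phen["phenotype"].to_numpy(),
        K=A,
        record_ids=record_ids,
        sigma2_a=h2,
        sigma2_e=max(1.0 - h2, 1e-6),
        weights=np.full(len(record_ids), float(n_parities)),
        X=X,
        fixed_names=["mu"] + [f"line:{lev}" for lev in levels[1:]],
    )
    line_map = ped.line_map()
    tr = TraitTable(pd.DataFrame({
        "animal": A.animal_ids,
        "line": [line_map[a] for a in A.animal_ids],
        "ebv": sol.g_hat,
        "r2": np.clip(sol.reliability, 0.01, 0.99),
    }))
    line_effects = {levels[0]: 0.0}
    for j, lev in enumerate(levels[1:], start=1):
        line_effects[lev] = float(sol.beta[j])
    return tr, line_effects


# ---------------------------------------------------------------------------
# full dataset generation


def _breed_generations(base: GenotypeMatrix, lab: str, n_offspring_per_gen, rng,
                       sire_frac: float = 0.25, start_gen: int = 1):
    """Random matings within a line for successive generations.

    Returns (genotype matrices per generation, pedigree rows).  Parents of
    generation g are the animals of generation g-1 (base for g=1), split
    into sires (first ``sire_frac``) and dams.
    """
    ped_rows = []
    gens = []
    parents = base
    for g, n_off in enumerate(n_offspring_per_gen, start=start_gen):
        n_par = parents.n_animals
        n_sires = max(2, int(round(sire_frac * n_par)))
        sire_pool = np.arange(n_sires)
        dam_pool = np.arange(n_sires, n_par)
        sires = rng.choice(sire_pool, size=n_off, replace=True)
        dams = rng.choice(dam_pool, size=n_off, replace=True)
        dos = np.empty((n_off, parents.n_snps))
        for i in range(n_off):
            dos[i] = _mate(parents.dosages, parents.dosages, sires[i], dams[i], rng)
        ids = np.array([f"{lab}_G{g}_{i + 1:05d}" for i in range(n_off)], dtype=object)
        gm = GenotypeMatrix(
            dosages=dos, animal_ids=ids, snp_ids=parents.snp_ids,
            lines=np.full(n_off, lab, dtype=object),
            chrom=parents.chrom, pos=parents.pos,
        )
        ped_rows.append(pd.DataFrame({
            "animal": ids,
            "sire": parents.animal_ids[sires],
            "dam": parents.animal_ids[dams],
            "line": lab,
        }))
        gens.append(gm)
        parents = gm
    return gens, pd.concat(ped_rows, ignore_index=True) if ped_rows else pd.DataFrame(
        columns=["animal", "sire", "dam", "line"])


def _concat_genotypes(mats: list[GenotypeMatrix]) -> GenotypeMatrix:
    return GenotypeMatrix(
        dosages=np.vstack([m.dosages for m in mats]),
        animal_ids=np.concatenate([m.animal_ids for m in mats]),
        snp_ids=mats[0].snp_ids,
        lines=np.concatenate([m.lines for m in mats]),
        chrom=mats[0].chrom,
        pos=mats[0].pos,
    )


@dataclass
class PopulationStructure:
    """Genotypes, pedigree and drifted frequencies, before any trait model.

    ``all_by_line`` holds every pedigree animal's genotypes per line;
    ``cohorts`` the genotyped (emitted) cohort per purebred line; ``gap_ids``
    the ungenotyped, unphenotyped multiplication-tier animals that separate
    the purebred cohorts from the F1 parents (connectors only).  Effects,
    phenotypes and pseudo-EBVs are layered on top by ``simulate_dataset``;
    exposing the split lets several trait architectures share one structure.
    """

    all_by_line: dict
    cohorts: dict
    pedigree: PedigreeTable
    line_freqs: dict
    founder_freqs: np.ndarray
    realized_fst: float
    gap_ids: set


def simulate_structure(spec: PopulationSpec) -> PopulationStructure:
    """Generate the population structure (no trait model attached)."""
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(6)]
    r_founder, r_drift, r_breed, r_f1, _, _ = rngs

    founders, p0 = simulate_founders(spec, rng=r_founder)
    line_freqs, fst = drift_frequencies(
        p0, spec.drift_generations, spec.effective_size, len(spec.lines), r_drift
    )
    line_freqs = dict(zip(spec.lines, line_freqs))

    ped_parts = []
    cohorts = {}          # line -> genotyped cohort matrix
    all_by_line = {}      # line -> every pedigree animal's genotypes
    f1_parent_pools = {}
    gap_ids: set = set()
    for lab in spec.lines:
        p = line_freqs[lab]
        n_base = spec.n_base_per_line
        dos = r_breed.binomial(2, p, size=(n_base, spec.n_snps)).astype(float)
        base = GenotypeMatrix(
            dosages=dos,
            animal_ids=np.array([f"{lab}_B{i + 1:05d}" for i in range(n_base)], dtype=object),
            snp_ids=founders.snp_ids,
            lines=np.full(n_base, lab, dtype=object),
            chrom=founders.chrom, pos=founders.pos,
        )
        ped_parts.append(pd.DataFrame({
            "animal": base.animal_ids,
            "sire": UNKNOWN_PARENT, "dam": UNKNOWN_PARENT, "line": lab,
        }))
        n1 = spec.n_per_line // 2
        n2 = spec.n_per_line - n1
        gens, rows = _breed_generations(base, lab, [n1, n2], r_breed)
        ped_parts.append(rows)
        cohort = _concat_genotypes(gens)
        cohorts[lab] = cohort
        all_by_line[lab] = _concat_genotypes([base] + gens)
        # optional ungenotyped generations separating purebreds from F1 parents
        pool = gens[-1]
        # the multiplication tier exists only to separate purebreds from F1
        if spec.gap_generations > 0 and spec.n_f1 > 0:
            gap, gap_rows = _breed_generations(
                pool, lab, [max(pool.n_animals, 50)] * spec.gap_generations,
                r_breed, start_gen=3,
            )
            ped_parts.append(gap_rows)
            all_by_line[lab] = _concat_genotypes([all_by_line[lab]] + gap)
            for gm_gap in gap:
                gap_ids.update(gm_gap.animal_ids)
            pool = gap[-1]
        f1_parent_pools[lab] = pool

    if spec.n_f1 > 0:
        f1_gm, f1_rows = make_f1(
            f1_parent_pools[spec.lines[0]], f1_parent_pools[spec.lines[1]],
            spec.n_f1, rng=r_f1,
            n_sires=spec.f1_n_sires, n_dams=spec.f1_n_dams,
            f1_line=spec.f1_line,
        )
        ped_parts.append(f1_rows)
        all_by_line[spec.f1_line] = f1_gm
    pedigree = PedigreeTable(pd.concat(ped_parts, ignore_index=True))
    return PopulationStructure(
        all_by_line=all_by_line, cohorts=cohorts, pedigree=pedigree,
        line_freqs=line_freqs, founder_freqs=p0, realized_fst=fst,
        gap_ids=gap_ids,
    )


def simulate_dataset(spec: PopulationSpec) -> SimulatedData:
    """Generate the full working set: genotypes, pedigree, traits, truth.

    Deterministic in (spec, spec.seed): identical inputs give bit-identical
    outputs.  Multiplication-tier (gap) animals separating the genotyped
    purebred cohorts from the F1 parents are phenotyped (commercial sows
    carry reproduction records) but never genotyped, so they inform the
    evaluation without entering any training or validation set.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(6)]
    _, _, _, _, r_trait, r_miss = rngs
    struct = simulate_structure(spec)
    cohorts, pedigree = struct.cohorts, struct.pedigree

    truth, phen = assign_effects_and_phenotypes(struct.all_by_line, spec, rng=r_trait)
    truth.line_freqs = struct.line_freqs
    truth.founder_freqs = struct.founder_freqs
    truth.realized_fst = struct.realized_fst

    traits, line_effects = pedblup_ebvs(phen, pedigree, spec.h2,
                                        n_parities=spec.n_parities)

    emitted = [cohorts[lab] for lab in spec.lines]
    if spec.n_f1 > 0:
        emitted.append(struct.all_by_line[spec.f1_line])
    genotypes = _concat_genotypes(emitted)
    # the trait table spans the whole pedigree (as a routine evaluation
    # would); alignment against genotypes narrows it to the analysis set
    if spec.missing_rate > 0:
        mask = r_miss.random(genotypes.dosages.shape) < spec.missing_rate
        dos = genotypes.dosages.copy()
        dos[mask] = np.nan
        genotypes = GenotypeMatrix(
            dosages=dos, animal_ids=genotypes.animal_ids, snp_ids=genotypes.snp_ids,
            lines=genotypes.lines, chrom=genotypes.chrom, pos=genotypes.pos,
        )
    return SimulatedData(
        spec=spec, genotypes=genotypes, pedigree=pedigree, traits=traits,
        phenotypes=phen, truth=truth, line_effects=line_effects,
    )


def write_truth(truth: SimTruth, path) -> None:
    """Sidecar CSV of per-animal true breeding values (test oracle)."""
    pd.DataFrame({
        "animal": truth.true_bv_pb.index,
        "tbv_pb": np.round(truth.true_bv_pb.to_numpy(), 10),
        "tbv_cb": np.round(truth.true_bv_cb.to_numpy(), 10),
    }).to_csv(path, index=False)
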