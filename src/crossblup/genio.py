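"""Readers, writers and containers for the file formats the pipeline touches.

Three tabular inputs drive every analysis: a genotype dosage matrix
(animals x SNPs, entries 0/1/2 counting alternate alleles, NaN for missing),
a pedigree (animal, sire, dam, line) and a trait table (animal, line, EBV,
reliability, optionally DEBV and residual weight).  Genotypes round-trip
through VCF (GT fields only) and through a PLINK-raw-style text dosage table;
pedigree and traits through CSV.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

UNKNOWN_PARENT = "0"
RAW_MISSING = "NA"


class DataError(ValueError):
    """Raised when an input file or container violates its contract."""


def _check_unique(values, what: str) -> None:
    values = np.asarray(values)
    uniq, counts = np.unique(values, return_counts=True)
    if (counts > 1).any():
        dups = uniq[counts > 1][:5].tolist()
        raise DataError(f"duplicate {what}: {dups}")


@dataclass
class GenotypeMatrix:
    """Animals x SNPs dosage matrix with missing-data mask and metadata.

    dosages is float so that NaN encodes missing and mean-imputed values
    (2p) can be carried; every non-missing raw entry must be in {0, 1, 2}.
    """

    dosages: np.ndarray
    animal_ids: np.ndarray
    snp_ids: np.ndarray
    lines: np.ndarray | None = None
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        if self.dosages.ndim != 2:
            raise DataError("dosages must be 2-D (animals x SNPs)")
        n, m = self.dosages.shape
        if len(self.animal_ids) != n:
            raise DataError(f"{len(self.animal_ids)} animal ids for {n} rows")
        if len(self.snp_ids) != m:
            raise DataError(f"{len(self.snp_ids)} SNP ids for {m} columns")
        _check_unique(self.animal_ids, "animal ids")
        _check_unique(self.snp_ids, "SNP ids")
        if self.lines is not None:
            self.lines = np.asarray(self.lines, dtype=object)
            if len(self.lines) != n:
                raise DataError("lines length mismatch")
        if self.chrom is None:
            self.chrom = np.full(m, "0", dtype=object)
        else:
            self.chrom = np.asarray(self.chrom, dtype=object)
        if self.pos is None:
            self.pos = np.arange(1, m + 1, dtype=int)
        else:
            self.pos = np.asarray(self.pos, dtype=int)

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    def validate_raw(self) -> None:
        """Check every non-missing entry is an integer dosage in {0,1,2}."""
        vals = self.dosages[~self.missing_mask]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = vals[~np.isin(vals, (0.0, 1.0, 2.0))][:3]
            raise DataError(f"non-{{0,1,2}} dosages present: {bad}")

    def line_of(self, animal_id: str) -> str:
        if self.lines is None:
            raise DataError("no line labels attached")
        idx = np.flatnonzero(self.animal_ids == animal_id)
        if not idx.size:
            raise KeyError(animal_id)
        return self.lines[idx[0]]

    def allele_freq(self) -> np.ndarray:
        """Observed alternate-allele frequency per SNP from non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def subset(self, animals=None, snps=None) -> "GenotypeMatrix":
        """Row/column subset by ID (order of the given IDs is preserved)."""
        ai = np.arange(self.n_animals)
        si = np.arange(self.n_snps)
        if animals is not None:
            lookup = {a: i for i, a in enumerate(self.animal_ids)}
            try:
                ai = np.array([lookup[a] for a in animals], dtype=int)
            except KeyError as e:
                raise DataError(f"animal not in genotype matrix: {e.args[0]}")
        if snps is not None:
            lookup = {s: i for i, s in enumerate(self.snp_ids)}
            si = np.array([lookup[s] for s in snps], dtype=int)
        return GenotypeMatrix(
            dosages=self.dosages[np.ix_(ai, si)],
            animal_ids=self.animal_ids[ai],
            snp_ids=self.snp_ids[si],
            lines=None if self.lines is None else self.lines[ai],
            chrom=self.chrom[si],
            pos=self.pos[si],
        )

    def with_lines(self, line_map: dict) -> "GenotypeMatrix":
        lines = np.array([line_map.get(a, "") for a in self.animal_ids], dtype=object)
        return replace(self, lines=lines)


@dataclass
class PedigreeTable:
    """Pedigree records (animal, sire, dam, line) in topological order.

    Unknown parents are the sentinel "0".  Construction topologically sorts
    the rows (parents before offspring) and rejects cycles.
    """

    df: pd.DataFrame

    COLUMNS = ("animal", "sire", "dam", "line")

    def __post_init__(self) -> None:
        df = self.df.copy()
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise DataError(f"pedigree missing columns {sorted(missing)}")
        for c in ("animal", "sire", "dam", "line"):
            df[c] = df[c].astype(str)
        df.loc[df["sire"].isin(("", "nan", "None")), "sire"] = UNKNOWN_PARENT
        df.loc[df["dam"].isin(("", "nan", "None")), "dam"] = UNKNOWN_PARENT
        _check_unique(df["animal"].to_numpy(), "pedigree animals")
        self.df = self._toposort(df).reset_index(drop=True)

    @staticmethod
    def _toposort(df: pd.DataFrame) -> pd.DataFrame:
        g = nx.DiGraph()
        g.add_nodes_from(df["animal"])
        known = set(df["animal"])
        for _, r in df.iterrows():
            for p in (r["sire"], r["dam"]):
                if p != UNKNOWN_PARENT and p in known:
                    g.add_edge(p, r["animal"])
        try:
            order = list(nx.topological_sort(g))
        except nx.NetworkXUnfeasible:
            cycle = nx.find_cycle(g)
            raise DataError(f"pedigree contains a cycle: {cycle}")
        # stable: keep original relative order among rows at the same depth
        rank = {a: i for i, a in enumerate(order)}
        return df.iloc[np.argsort([rank[a] for a in df["animal"]], kind="stable")]

    @property
    def animals(self) -> np.ndarray:
        return self.df["animal"].to_numpy(dtype=object)

    def line_map(self) -> dict:
        return dict(zip(self.df["animal"], self.df["line"]))

    def parents_of(self, animal: str) -> tuple[str, str]:
        row = self.df.loc[self.df["animal"] == animal]
        if row.empty:
            raise KeyError(animal)
        return row["sire"].iloc[0], row["dam"].iloc[0]


@dataclass
class TraitTable:
    """Per-animal EBV and reliability, optionally DEBV and residual weight."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        needed = {"animal", "line", "ebv", "r2"}
        missing = needed - set(df.columns)
        if missing:
            raise DataError(f"trait table missing columns {sorted(missing)}")
        df["animal"] = df["animal"].astype(str)
        df["line"] = df["line"].astype(str)
        _check_unique(df["animal"].to_numpy(), "trait animals")
        r2 = df["r2"].to_numpy(dtype=float)
        if ((r2 <= 0) | (r2 > 1)).any():
            bad = df["animal"][(r2 <= 0) | (r2 > 1)].tolist()[:5]
            raise DataError(f"reliability outside (0,1] for animals {bad}")
        has_debv = "debv" in df.columns and df["debv"].notna().any()
        has_w = "weight" in df.columns and df["weight"].notna().any()
        if has_debv != has_w:
            raise DataError("debv and weight must be present together")
        if has_w and (df["weight"].to_numpy(dtype=float) <= 0).any():
            raise DataError("weights must be positive")
        self.df = df.reset_index(drop=True)

    @property
    def animals(self) -> np.ndarray:
        return self.df["animal"].to_numpy(dtype=object)

    @property
    def has_debv(self) -> bool:
        return "debv" in self.df.columns and self.df["debv"].notna().any()


# ---------------------------------------------------------------------------
# genotype I/O


def write_genotypes(gm: GenotypeMatrix, path, format: str = "vcf") -> None:
    if format == "vcf":
        _write_vcf(gm, path)
    elif format == "raw":
        _write_raw(gm, path)
    else:
        raise DataError(f"unknown genotype format {format!r}")


def read_genotypes(path, format: str = "vcf") -> GenotypeMatrix:
    if format == "vcf":
        return _read_vcf(path)
    if format == "raw":
        return _read_raw(path)
    raise DataError(f"unknown genotype format {format!r}")


_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def _write_vcf(gm: GenotypeMatrix, path) -> None:
    gm.validate_raw()
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write("##source=crossblup\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    for c in dict.fromkeys(gm.chrom):
        buf.write(f"##contig=<ID={c}>\n")
    samples = "\t".join(str(a) for a in gm.animal_ids)
    buf.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
    # placeholder alleles: the pipeline carries dosages, not nucleotides
    for j in range(gm.n_snps):
        col = gm.dosages[:, j]
        gts = "\t".join("./." if np.isnan(d) else _GT_CODE[d] for d in col)
        buf.write(
            f"{gm.chrom[j]}\t{gm.pos[j]}\t{gm.snp_ids[j]}\tA\tG\t.\t.\t.\tGT\t{gts}\n"
        )
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.array(vcf.samples, dtype=object)
    _check_unique(samples, "VCF sample ids")
    snp_ids, chrom, pos, cols = [], [], [], []
    for k, var in enumerate(vcf):
        if len(var.ALT) > 1:
            raise DataError(
                f"multi-allelic site {var.ID or var.POS} (record {k + 1}) unsupported"
            )
        snp_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        chrom.append(var.CHROM)
        pos.append(var.POS)
        col = np.empty(len(samples))
        for i, g in enumerate(var.genotypes):
            a = g[:-1]  # trailing element is phasing flag
            if len(a) != 2 or a[0] < 0 or a[1] < 0:
                col[i] = np.nan
            else:
                col[i] = a[0] + a[1]
        cols.append(col)
    vcf.close()
    if not cols:
        raise DataError(f"no variant records in {path}")
    _check_unique(np.array(snp_ids, dtype=object), "VCF SNP ids")
    return GenotypeMatrix(
        dosages=np.column_stack(cols),
        animal_ids=samples,
        snp_ids=np.array(snp_ids, dtype=object),
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=int),
    )


def _write_raw(gm: GenotypeMatrix, path) -> None:
    lines = gm.lines if gm.lines is not None else np.full(gm.n_animals, "", dtype=object)
    df = pd.DataFrame(gm.dosages, columns=list(gm.snp_ids))
    df.insert(0, "line", lines)
    df.insert(0, "animal_id", gm.animal_ids)
    df.to_csv(path, sep="\t", index=False, na_rep=RAW_MISSING)


def _read_raw(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values=[RAW_MISSING], dtype={"animal_id": str})
    if "animal_id" not in df.columns:
        raise DataError("raw dosage table must have an 'animal_id' column")
    has_line = "line" in df.columns
    snp_cols = [c for c in df.columns if c not in ("animal_id", "line")]
    try:
        dosages = df[snp_cols].to_numpy(dtype=float)
    except ValueError as e:
        raise DataError(f"non-numeric dosage in {path}: {e}")
    # real-valued entries in [0, 2] are legal (mean-imputed dosages)
    ok = np.isnan(dosages) | ((dosages >= 0.0) & (dosages <= 2.0))
    bad = np.flatnonzero(~ok.all(axis=1))
    if bad.size:
        raise DataError(f"malformed dosage on data line {bad[0] + 2} of {path}")
    lines = df["line"].astype(str).to_numpy(dtype=object) if has_line else None
    return GenotypeMatrix(
        dosages=dosages,
        animal_ids=df["animal_id"].to_numpy(dtype=object),
        snp_ids=np.array(snp_cols, dtype=object),
        lines=lines,
    )


# ---------------------------------------------------------------------------
# pedigree / trait I/O


def read_pedigree(path) -> PedigreeTable:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return PedigreeTable(df)


def write_pedigree(ped: PedigreeTable, path) -> None:
    ped.df.to_csv(path, index=False)


def read_traits(path) -> TraitTable:
    df = pd.read_csv(path, dtype={"animal": str, "line": str})
    return TraitTable(df)


def write_traits(tr: TraitTable, path) -> None:
    df = tr.df.copy()
    num = df.select_dtypes(include=[np.number]).columns
    df[num] = df[num].round(10)  # canonical form so reruns are byte-identical
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# dataset alignment


@dataclass
class AlignmentReport:
    n_common: int
    genotype_only: int = 0
    trait_only: int = 0
    not_in_pedigree: int = 0
    dropped_genotype_ids: list = field(default_factory=list)
    dropped_trait_ids: list = field(default_factory=list)


def align_datasets(
    g: GenotypeMatrix, ped: PedigreeTable, tr: TraitTable
) -> tuple[GenotypeMatrix, TraitTable, AlignmentReport]:
    """Intersect genotyped animals with trait records; keep the full pedigree.

    Returns the genotype subset and trait subset over the common animals (in
    genotype-matrix order) and a report of what was dropped from each source.
    """
    gset = set(g.animal_ids)
    tset = set(tr.animals)
    common = [a for a in g.animal_ids if a in tset]
    if not common:
        raise DataError("no animal has both genotypes and trait records")
    report = AlignmentReport(
        n_common=len(common),
        genotype_only=len(gset - tset),
        trait_only=len(tset - gset),
        not_in_pedigree=len([a for a in common if a not in set(ped.animals)]),
        dropped_genotype_ids=sorted(gset - tset)[:20],
        dropped_trait_ids=sorted(tset - gset)[:20],
    )
    g2 = g.subset(animals=common)
    if g2.lines is None:
        g2 = g2.with_lines(ped.line_map())
    t2 = TraitTable(tr.df[tr.df["animal"].isin(common)].set_index("animal").loc[common].reset_index())
    return g2, t2, report
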