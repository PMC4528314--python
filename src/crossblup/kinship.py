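"""Pedigree (A) and genomic (G) relationship matrices.

The numerator relationship matrix A is built by the tabular method from a
topologically ordered pedigree.  The genomic matrix G follows VanRaden's
first method, G = ZZ' / (2 * sum_i p_i q_i) with Z the column-centered
dosage matrix.  For data pooling several genetic lines, an across-population
variant centers each animal's genotypes with its own line's allele
frequencies, so that mean differences between lines do not masquerade as
relatedness; the denominator is either blockwise (sqrt(d_j d_k) per line
pair, preserving each line's own VanRaden block exactly) or a single pooled
2*sum(p_bar q_bar).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import DataError, GenotypeMatrix, PedigreeTable, UNKNOWN_PARENT


@dataclass
class RelationshipMatrix:
    """Symmetric animals x animals relationship matrix keyed by animal IDs."""

    values: np.ndarray
    animal_ids: np.ndarray
    kind: str  # pedigree | genomic_within | genomic_across
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        n = len(self.animal_ids)
        if self.values.shape != (n, n):
            raise DataError("relationship matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise DataError("relationship matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.animal_ids)

    def index_of(self, ids) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.animal_ids)}
        try:
            return np.array([lookup[a] for a in ids], dtype=int)
        except KeyError as e:
            raise DataError(f"animal {e.args[0]!r} not in relationship matrix")

    def subset(self, ids) -> "RelationshipMatrix":
        idx = self.index_of(ids)
        return RelationshipMatrix(
            values=self.values[np.ix_(idx, idx)],
            animal_ids=self.animal_ids[idx],
            kind=self.kind,
            meta=dict(self.meta),
        )


def build_A(ped: PedigreeTable, subset=None) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    a_ii = 1 + 0.5 * a(sire, dam); a_ij = 0.5 * (a_j,sire(i) + a_j,dam(i))
    for previously processed j; unknown parents contribute zero.  When
    ``subset`` is given, the full recursion over all ancestors is retained
    and the submatrix for the requested animals returned.
    """
    animals = ped.animals
    idx = {a: i for i, a in enumerate(animals)}
    n = len(animals)
    A = np.zeros((n, n))
    sires = ped.df["sire"].to_numpy(dtype=object)
    dams = ped.df["dam"].to_numpy(dtype=object)
    for i in range(n):
        s, d = sires[i], dams[i]
        si = idx.get(s, -1) if s != UNKNOWN_PARENT else -1
        di = idx.get(d, -1) if d != UNKNOWN_PARENT else -1
        row = np.zeros(n)
        if si >= 0:
            row[:i] += 0.5 * A[si, :i]
        if di >= 0:
            row[:i] += 0.5 * A[di, :i]
        A[i, :i] = row[:i]
        A[:i, i] = row[:i]
        A[i, i] = 1.0 + (0.5 * A[si, di] if (si >= 0 and di >= 0) else 0.0)
    rm = RelationshipMatrix(values=A, animal_ids=animals, kind="pedigree")
    if subset is not None:
        missing = [a for a in subset if a not in idx]
        if missing:
            raise DataError(f"animals absent from pedigree: {missing[:5]}")
        rm = rm.subset(subset)
    return rm


def _vanraden_parts(dosages: np.ndarray, p: np.ndarray):
    Z = dosages - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    return Z, denom


def build_G_vanraden(g: GenotypeMatrix, freqs=None) -> RelationshipMatrix:
    """VanRaden G = ZZ' / (2 sum p_i q_i) with Z = dosage - 2p.

    ``freqs``: per-SNP allele frequencies used for centering and scaling;
    default is the observed frequencies of the analyzed animals (in which
    case every row of G sums to zero).
    """
    X = g.dosages
    if np.isnan(X).any():
        raise DataError("G construction requires complete (imputed) genotypes")
    p = g.allele_freq() if freqs is None else np.asarray(freqs, dtype=float)
    if p.shape != (g.n_snps,):
        raise DataError("frequency vector length mismatch")
    Z, denom = _vanraden_parts(X, p)
    if denom <= 0:
        raise DataError("all SNPs monomorphic: 2*sum(pq) = 0")
    G = (Z @ Z.T) / denom
    return RelationshipMatrix(
        values=G,
        animal_ids=g.animal_ids,
        kind="genomic_within",
        meta={"center_freqs": p, "denominator": denom, "freq_source": "observed" if freqs is None else "supplied"},
    )


def build_G_across(
    g: GenotypeMatrix,
    denominator: str = "blockwise",
    line_freqs: dict | None = None,
    min_line_n: int = 2,
) -> RelationshipMatrix:
    """Across-population G: per-line allele-frequency centering.

    Each animal's genotypes are centered with its own line's frequencies
    (supplied via ``line_freqs`` or observed within line).  With
    ``denominator="blockwise"`` the (line j, line k) block is divided by
    sqrt(d_j * d_k), d_l = 2 sum p_l q_l, so each within-line block equals
    that line's own VanRaden G; ``"pooled"`` divides everything by the single
    2 sum p_bar q_bar from pooled frequencies.
    """
    if g.lines is None:
        raise DataError("across-population G requires line labels")
    X = g.dosages
    if np.isnan(X).any():
        raise DataError("G construction requires complete (imputed) genotypes")
    if denominator not in ("blockwise", "pooled"):
        raise DataError(f"unknown denominator rule {denominator!r}")
    labels = pd.unique(pd.Series(g.lines))
    if len(labels) < 2 and line_freqs is None:
        # degenerate single-line input: collapses to the VanRaden matrix
        rm = build_G_vanraden(g)
        rm.kind = "genomic_across"
        rm.meta["denominator_rule"] = denominator
        return rm
    freqs, d = {}, {}
    for lab in labels:
        mask = g.lines == lab
        if line_freqs is not None and lab in line_freqs:
            p = np.asarray(line_freqs[lab], dtype=float)
        elif mask.sum() >= min_line_n:
            p = X[mask].mean(axis=0) / 2.0
        else:
            raise DataError(
                f"line {lab!r} has {mask.sum()} animals; supply line_freqs to use it"
            )
        freqs[lab] = p
        d[lab] = 2.0 * np.sum(p * (1.0 - p))
        if d[lab] <= 0:
            raise DataError(f"line {lab!r}: 2*sum(pq) = 0")
    Z = np.empty_like(X)
    for lab in labels:
        mask = g.lines == lab
        Z[mask] = X[mask] - 2.0 * freqs[lab]
    ZZt = Z @ Z.T
    if denominator == "pooled":
        pbar = X.mean(axis=0) / 2.0
        dp = 2.0 * np.sum(pbar * (1.0 - pbar))
        G = ZZt / dp
        scale_meta = {"pooled_denominator": dp}
    else:
        scale = np.array([np.sqrt(d[lab]) for lab in g.lines])
        G = ZZt / np.outer(scale, scale)
        scale_meta = {"block_denominators": d}
    return RelationshipMatrix(
        values=G,
        animal_ids=g.animal_ids,
        kind="genomic_across",
        meta={"line_freqs": freqs, "denominator_rule": denominator, **scale_meta,
              "lines": np.asarray(g.lines, dtype=object)},
    )


def f1_line_freqs(g: GenotypeMatrix, f1_line: str, parent_lines: tuple[str, str],
                  min_f1: int = 30) -> np.ndarray:
    """Allele frequencies to use for an F1 line when centering across-G.

    Observed F1 frequencies when at least ``min_f1`` F1 animals are present,
    else the mean of the two parental lines' observed frequencies.
    """
    if g.lines is None:
        raise DataError("line labels required")
    mask = g.lines == f1_line
    if mask.sum() >= min_f1:
        return g.dosages[mask].mean(axis=0) / 2.0
    pa = g.dosages[g.lines == parent_lines[0]].mean(axis=0) / 2.0
    pb = g.dosages[g.lines == parent_lines[1]].mean(axis=0) / 2.0
    return 0.5 * (pa + pb)


def stabilize(K: np.ndarray, min_eig: float = 1e-8) -> tuple[np.ndarray, float]:
    """Add eps*I (eps = 1e-6 * mean diagonal) when K is near-singular.

    Genomic matrices from finite SNP panels can be singular; the returned
    epsilon (0.0 when no perturbation was needed) is recorded by callers.
    """
    w = np.linalg.eigvalsh(K)
    if w[0] < min_eig:
        eps = 1e-6 * float(np.mean(np.diag(K)))
        return K + eps * np.eye(K.shape[0]), eps
    return K, 0.0


def mean_relatedness_split(
    K: RelationshipMatrix, training_ids, validation_ids, fraction: float = 0.5
) -> tuple[list, list, pd.Series]:
    """Split training animals by mean relationship to the validation set.

    Each training animal is scored by its mean relationship to all validation
    animals; the top ``fraction`` (rounded down) are the MOST related half.
    Ties are broken by stable animal-ID order within the score sort.
    """
    training_ids = list(training_ids)
    validation_ids = list(validation_ids)
    if set(training_ids) & set(validation_ids):
        raise DataError("training and validation sets overlap")
    ti = K.index_of(training_ids)
    vi = K.index_of(validation_ids)
    scores = K.values[np.ix_(ti, vi)].mean(axis=1)
    s = pd.Series(scores, index=training_ids)
    order = np.argsort(-scores, kind="stable")
    n_most = int(np.floor(fraction * len(training_ids)))
    most = [training_ids[i] for i in order[:n_most]]
    least = [training_ids[i] for i in order[n_most:]]
    return most, least, s


# ---------------------------------------------------------------------------
# text serialization


def write_matrix(K: RelationshipMatrix, path) -> None:
    """Dense symmetric matrix with an ID header row."""
    df = pd.DataFrame(np.round(K.values, 10), index=K.animal_ids, columns=K.animal_ids)
    df.to_csv(path, index_label="animal")


def read_matrix(path, kind: str = "genomic_within") -> RelationshipMatrix:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    vals = df.to_numpy(dtype=float)
    vals = 0.5 * (vals + vals.T)  # symmetrize away round-trip rounding
    return RelationshipMatrix(values=vals, animal_ids=df.index.to_numpy(dtype=object), kind=kind)


def write_sparse(K: RelationshipMatrix, path, lower: bool = True) -> None:
    """Three-column (id_i, id_j, value) lower-triangle text form."""
    i, j = np.tril_indices(K.n) if lower else np.indices((K.n, K.n)).reshape(2, -1)
    pd.DataFrame(
        {
            "id_i": K.animal_ids[i],
            "id_j": K.animal_ids[j],
            "value": np.round(K.values[i, j], 10),
        }
    ).to_csv(path, index=False)
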