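"""Deregression of EBVs into pseudo-phenotypes (DEBV) with residual weights.

An EBV is a shrunken, partly parent-derived estimate of an animal's additive
genetic merit.  Using EBVs directly as responses in genomic prediction
double-counts family information and under-disperses the signal, so they are
deregressed: the shrinkage is undone and (in ``parent_adjusted`` mode) the
parent-average contribution removed, leaving a pseudo-record that reflects
the animal's own information.  Records then enter the mixed model with
heterogeneous residual variance sigma2_e / w_i, where the weight

    w = (1 - h2) / ((c + (1 - r2) / r2) * h2)

grows with the reliability r2 of the deregressed proof; c is the fraction of
genetic variance not captured by markers (default 0).

``parent_adjusted`` mode solves, per animal, the two-unknown information
system implied by lambda = (1 - h2) / h2: find the parent-average and
own-record information contents (Z'Z_PA, Z'Z_i) such that the two-effect
mixed-model equations

    [ Z'Z_PA + 4*lambda   -2*lambda  ] [ g_PA ]   [ y*_PA ]
    [ -2*lambda        Z'Z_i + 2*lambda ] [ g_i ] = [ y*_i  ]

(whose lambda terms are the inverse of the relationship matrix
[[0.5, 0.5], [0.5, 1]] between parent average and individual) reproduce the
input EBV and reliability exactly, with r2_i = 1 - lambda*C_22 and
r2_PA = 1 - 2*lambda*C_11 for C the inverse coefficient matrix.  The DEBV is
the solved own-information pseudo-record y*_i / Z'Z_i and its reliability is
Z'Z_i / (Z'Z_i + lambda).  This round trip is the defining contract and the
test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import DataError, PedigreeTable, TraitTable, UNKNOWN_PARENT


@dataclass
class DeregressionResult:
    table: TraitTable            # input columns + debv, weight, r2_debv
    mode: str
    h2: float
    c: float
    n_fallback_simple: int       # parent_adjusted records lacking usable parents
    line_effect_added: dict | None = None
    log: list | None = None


def weights(r2, h2: float, c: float = 0.0, cap_r2: float | None = None):
    """Garrick-style residual weight w = (1-h2)/((c + (1-r2)/r2) * h2).

    Monotone increasing in r2 and decreasing in h2.  With c = 0 the weight
    diverges as r2 -> 1; pass ``cap_r2`` (e.g. 0.99) to cap reliabilities
    before evaluation, else r2 >= 1 with c = 0 raises.
    """
    r2 = np.asarray(r2, dtype=float)
    scalar = r2.ndim == 0
    r2 = np.atleast_1d(r2)
    if not 0 < h2 < 1:
        raise DataError(f"h2 must be in (0,1), got {h2}")
    if c < 0:
        raise DataError("c must be >= 0")
    if ((r2 <= 0) | (r2 > 1)).any():
        raise DataError("reliabilities must be in (0,1]")
    if cap_r2 is not None:
        r2 = np.minimum(r2, cap_r2)
    if c == 0 and (r2 >= 1).any():
        raise DataError(
            "r2 = 1 with c = 0 gives an infinite weight; cap the reliability "
            "(cap_r2=0.99) or use c > 0"
        )
    w = (1.0 - h2) / ((c + (1.0 - r2) / r2) * h2)
    return float(w[0]) if scalar else w


def _solve_information(r2_pa: float, r2_i: float, lam: float) -> tuple[float, float]:
    """Solve for (Z'Z_PA, Z'Z_i) reproducing the given reliabilities.

    ``r2_pa`` is the parent-average reliability in the predictor-of-the-
    individual convention, (r2_sire + r2_dam)/4 < 0.5; internally it is
    doubled into the reliability of the PA estimate with respect to the PA
    effect itself (whose variance is sigma2_a / 2).  With
    u = Z'Z_PA + 4*lambda, v = Z'Z_i + 2*lambda, det = u*v - 4*lambda^2,
    the inverse coefficient matrix gives 1 - 2*r2_pa = 2*lambda*v/det and
    1 - r2_i = lambda*u/det, which reduce to u = 2*rho*v with
    rho = (1-r2_i)/(1-2*r2_pa) and a quadratic in v.  Returns (nan, nan)
    when the reliability pair is infeasible (non-positive information).
    """
    if not (0 <= r2_pa < 0.5) or not (0 < r2_i < 1):
        return np.nan, np.nan
    r2_pa_est = 2.0 * r2_pa
    rho = (1.0 - r2_i) / (1.0 - r2_pa_est)
    a_coef = 2.0 * rho * (1.0 - r2_i)
    b_coef = -2.0 * lam * rho
    c_coef = -4.0 * lam**2 * (1.0 - r2_i)
    disc = b_coef**2 - 4.0 * a_coef * c_coef
    v = (-b_coef + np.sqrt(disc)) / (2.0 * a_coef)
    u = 2.0 * rho * v
    zz_pa = u - 4.0 * lam
    zz_i = v - 2.0 * lam
    if zz_i <= 0 or zz_pa < 0:
        return np.nan, np.nan
    return zz_pa, zz_i


def two_effect_mme(zz_pa: float, zz_i: float, lam: float):
    """Coefficient matrix and inverse of the PA/individual two-effect system."""
    lhs = np.array([[zz_pa + 4 * lam, -2 * lam], [-2 * lam, zz_i + 2 * lam]])
    cinv = np.linalg.inv(lhs)
    return lhs, cinv


def deregress(
    tr: TraitTable,
    ped: PedigreeTable | None = None,
    h2: float = 0.3,
    c: float = 0.0,
    mode: str = "parent_adjusted",
    cap_r2: float = 0.99,
) -> DeregressionResult:
    """Deregress every trait record; attach debv, weight and r2_debv columns.

    mode="simple": DEBV = EBV / r2, reliability unchanged.
    mode="parent_adjusted": remove the parent-average contribution via the
    two-effect information system (requires a pedigree and both parents with
    EBV records; animals without them fall back to simple mode, logged).
    """
    if mode not in ("simple", "parent_adjusted"):
        raise DataError(f"unknown deregression mode {mode!r}")
    if not 0 < h2 < 1:
        raise DataError(f"h2 must be in (0,1), got {h2}")
    if mode == "parent_adjusted" and ped is None:
        raise DataError("parent_adjusted mode requires a pedigree")
    df = tr.df.copy()
    lam = (1.0 - h2) / h2
    ebv = df["ebv"].to_numpy(dtype=float)
    r2 = df["r2"].to_numpy(dtype=float)
    if (r2 <= 0).any():
        raise DataError("zero reliability: no information to deregress")
    debv = np.empty(len(df))
    r2_out = np.empty(len(df))
    used_mode = np.full(len(df), "simple", dtype=object)
    pa_arr = np.full(len(df), np.nan)
    zz_pa_arr = np.full(len(df), np.nan)
    zz_i_arr = np.full(len(df), np.nan)
    n_fallback = 0
    if mode == "simple":
        debv = ebv / r2
        r2_out = r2.copy()
    else:
        by_animal = dict(zip(df["animal"], zip(ebv, r2)))
        sires = dict(zip(ped.df["animal"], ped.df["sire"]))
        dams = dict(zip(ped.df["animal"], ped.df["dam"]))
        for k, animal in enumerate(df["animal"]):
            s = sires.get(animal, UNKNOWN_PARENT)
            d = dams.get(animal, UNKNOWN_PARENT)
            rec_s = by_animal.get(s) if s != UNKNOWN_PARENT else None
            rec_d = by_animal.get(d) if d != UNKNOWN_PARENT else None
            if rec_s is None and rec_d is None:
                debv[k] = ebv[k] / r2[k]
                r2_out[k] = r2[k]
                n_fallback += 1
                continue
            ebv_s, r2_s = rec_s if rec_s else (0.0, 0.0)
            ebv_d, r2_d = rec_d if rec_d else (0.0, 0.0)
            pa = 0.5 * (ebv_s + ebv_d)
            r2_pa = 0.25 * (r2_s + r2_d)
            zz_pa, zz_i = _solve_information(r2_pa, r2[k], lam)
            if not np.isfinite(zz_i):
                debv[k] = ebv[k] / r2[k]
                r2_out[k] = r2[k]
                n_fallback += 1
                continue
            lhs, _ = two_effect_mme(zz_pa, zz_i, lam)
            rhs = lhs @ np.array([pa, ebv[k]])
            debv[k] = rhs[1] / zz_i
            r2_out[k] = zz_i / (zz_i + lam)
            used_mode[k] = "parent_adjusted"
            pa_arr[k], zz_pa_arr[k], zz_i_arr[k] = pa, zz_pa, zz_i
    df["debv"] = debv
    df["r2_debv"] = r2_out
    df["weight"] = weights(r2_out, h2=h2, c=c, cap_r2=cap_r2)
    df["dereg_mode"] = used_mode
    if mode == "parent_adjusted":
        # diagnostics: parent average and solved information contents, the
        # quantities a round-trip check needs to rebuild the two-effect system
        df["parent_average"] = pa_arr
        df["zz_pa"] = zz_pa_arr
        df["zz_i"] = zz_i_arr
    log = [f"deregressed {len(df)} records, mode={mode}, h2={h2}, c={c}"]
    if n_fallback:
        log.append(f"{n_fallback} records fell back to simple mode (unusable parents)")
    return DeregressionResult(
        table=TraitTable(df), mode=mode, h2=h2, c=c,
        n_fallback_simple=n_fallback, log=log,
    )


def add_back_line_effect(tr: TraitTable, line_effects: dict, column: str | None = None) -> TraitTable:
    """Add each animal's estimated line effect back onto its (D)EBV.

    Line mean differences are removed as fixed effects during EBV
    estimation; re-introducing them before multi-population genomic
    prediction keeps between-line level differences in the data, so a line
    fixed effect must again be fitted downstream.  The adjusted table
    carries a ``line_effect_added`` column recording the shift.
    """
    df = tr.df.copy()
    unknown = set(df["line"]) - set(line_effects)
    if unknown:
        raise DataError(f"no line effect supplied for lines {sorted(unknown)}")
    if column is None:
        column = "debv" if ("debv" in df.columns and df["debv"].notna().any()) else "ebv"
    shift = df["line"].map(line_effects).to_numpy(dtype=float)
    df[column] = df[column].to_numpy(dtype=float) + shift
    df["line_effect_added"] = shift
    return TraitTable(df)
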