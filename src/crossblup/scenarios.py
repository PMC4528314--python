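"""Replicated training/validation designs for genomic prediction accuracy.

Seventeen scenario types cover four designs: within-population (training and
validation subsets of the same line), multi-population (the other purebred
line(s) added to the training set), across-population (one purebred line
predicting the other), and purebred-to-crossbred (purebred training, F1
validation).  Per replicate the validation animals' responses are removed,
GBLUP (or PED-BLUP) is fitted on the training records, and two statistics
are taken over the validation set: accuracy, the Pearson correlation between
predictions and DEBVs, and the dispersion bias, the OLS slope of DEBV on
GEBV (1 = unbiased; the reverse regression is also reported since both
conventions circulate).  Sampling depends only on the scenario id, base
seed and replicate index, so GBLUP and PED-BLUP see identical
training/validation splits and comparisons are paired.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import DataError, GenotypeMatrix, PedigreeTable, TraitTable
from .kinship import RelationshipMatrix, build_A, build_G_across, build_G_vanraden
from .varcomp import design_matrix, reml_univariate, solve_blup


# ---------------------------------------------------------------------------
# accuracy and bias


def accuracy(gebv, debv) -> float:
    """Pearson correlation between predictions and validation DEBVs.

    Returns NaN (the undefined-accuracy signal, distinct from 0) when either
    vector has zero variance.
    """
    gebv = np.asarray(gebv, dtype=float)
    debv = np.asarray(debv, dtype=float)
    if gebv.shape != debv.shape or gebv.ndim != 1 or len(gebv) < 3:
        raise DataError("accuracy needs paired vectors of length >= 3")
    if np.std(gebv) == 0 or np.std(debv) == 0:
        return float("nan")
    return float(np.corrcoef(gebv, debv)[0, 1])


def bias_slope(gebv, debv, direction: str = "debv_on_gebv") -> float:
    """OLS dispersion-bias slope; 1 means predictions are correctly dispersed.

    direction="debv_on_gebv" regresses the validation DEBVs on the
    predictions; "gebv_on_debv" is the reverse convention.
    """
    gebv = np.asarray(gebv, dtype=float)
    debv = np.asarray(debv, dtype=float)
    if gebv.shape != debv.shape or gebv.ndim != 1 or len(gebv) < 3:
        raise DataError("bias_slope needs paired vectors of length >= 3")
    x, y = (gebv, debv) if direction == "debv_on_gebv" else (debv, gebv)
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        return float("nan")
    return float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)


# ---------------------------------------------------------------------------
# working set and scenario definition


@dataclass
class WorkingSet:
    """Aligned post-QC genotypes, pedigree, and deregressed trait records."""

    genotypes: GenotypeMatrix
    pedigree: PedigreeTable
    traits: TraitTable
    response: str = "debv"
    _A: RelationshipMatrix | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.response not in self.traits.df.columns:
            raise DataError(f"trait table lacks the response column {self.response!r}")
        if "weight" not in self.traits.df.columns:
            raise DataError("trait table lacks residual weights; deregress first")
        missing = set(self.traits.animals) - set(self.genotypes.animal_ids)
        if missing:
            raise DataError(f"trait records without genotypes: {sorted(missing)[:5]}")

    def full_A(self) -> RelationshipMatrix:
        if self._A is None:
            self._A = build_A(self.pedigree)
        return self._A

    def eligible(self, line: str) -> list:
        df = self.traits.df
        ok = df[self.response].notna() & (df["line"] == line)
        return df.loc[ok, "animal"].tolist()


@dataclass
class ScenarioSpec:
    id: str
    group: int
    training_lines: dict            # line -> size (int) or "all"
    validation_line: str
    validation_size: object         # int or "all"
    n_replicates: int
    matrix: str                     # genomic_within | genomic_across | pedigree
    equalize_training_sizes: bool = False
    seed: int = 0

    def replicate_rngs(self):
        """Deterministic, pairwise-distinct streams shared across models."""
        entropy = (self.seed, zlib.crc32(self.id.encode()))
        return [np.random.default_rng(s)
                for s in np.random.SeedSequence(entropy).spawn(self.n_replicates)]


@dataclass
class ScenarioResult:
    spec: ScenarioSpec
    model: str                      # gblup | pedblup
    per_replicate: pd.DataFrame
    accuracy_mean: float
    accuracy_sd: float | None       # only when n_replicates > 1
    slope_mean: float
    slope_rev_mean: float
    n_undefined: int
    mean_r2_training: float
    skipped: str | None = None


# ---------------------------------------------------------------------------
# scenario execution


def _build_K(data: WorkingSet, ids, matrix: str, denominator: str) -> RelationshipMatrix:
    if matrix == "pedigree":
        return data.full_A().subset(ids)
    sub = data.genotypes.subset(animals=ids)
    if matrix == "genomic_within":
        return build_G_vanraden(sub)
    if matrix == "genomic_across":
        return build_G_across(sub, denominator=denominator)
    raise DataError(f"unknown matrix kind {matrix!r}")


def run_scenario(
    spec: ScenarioSpec,
    data: WorkingSet,
    model: str = "gblup",
    components="reml",
    denominator: str = "blockwise",
) -> ScenarioResult:
    """Run all replicates of one scenario and aggregate accuracy and bias.

    ``components``: "reml" re-estimates (sigma2_a, sigma2_e) on each
    replicate's training records; a (sigma2_a, sigma2_e) tuple fixes them.
    """
    if model not in ("gblup", "pedblup"):
        raise DataError(f"unknown model {model!r}")
    matrix = "pedigree" if model == "pedblup" else spec.matrix
    tr_df = data.traits.df.set_index("animal")
    rows = []
    rngs = spec.replicate_rngs()
    for rep, rng in enumerate(rngs):
        val_pool = data.eligible(spec.validation_line)
        if spec.validation_size == "all":
            val_ids = list(val_pool)
        else:
            k = int(spec.validation_size)
            if k > len(val_pool):
                raise DataError(
                    f"validation_size {k} exceeds the {len(val_pool)} eligible "
                    f"animals of line {spec.validation_line!r}"
                )
            val_ids = sorted(rng.choice(val_pool, size=k, replace=False).tolist())
        if len(val_ids) < 3:
            raise DataError("validation set smaller than 3")
        val_set = set(val_ids)
        train_ids, train_lines = [], []
        for line, size in spec.training_lines.items():
            pool = [a for a in data.eligible(line) if a not in val_set]
            if size == "all":
                chosen = pool
            else:
                size = int(size)
                if size > len(pool):
                    raise DataError(
                        f"training size {size} exceeds the {len(pool)} eligible "
                        f"animals of line {line!r}"
                    )
                chosen = sorted(rng.choice(pool, size=size, replace=False).tolist())
            train_ids.extend(chosen)
            train_lines.extend([line] * len(chosen))
        if set(train_ids) & val_set:
            raise DataError("training and validation sets overlap")

        ids = train_ids + val_ids
        K = _build_K(data, ids, matrix, denominator)
        y = tr_df.loc[train_ids, data.response].to_numpy(dtype=float)
        w = tr_df.loc[train_ids, "weight"].to_numpy(dtype=float)
        levels = list(dict.fromkeys(train_lines))
        if len(levels) > 1:
            X, levels = design_matrix(train_lines, levels=levels)
            X_val, _ = design_matrix(
                tr_df.loc[val_ids, "line"].to_numpy(), levels=levels
            )
        else:
            X = np.ones((len(y), 1))
            X_val = np.ones((len(val_ids), 1))
        if components == "reml":
            vc = reml_univariate(y, K, train_ids, weights=w, X=X)
            s2a, s2e = vc.sigma2_a, vc.sigma2_e
        else:
            s2a, s2e = components
        sol = solve_blup(
            y, K, train_ids, sigma2_a=s2a, sigma2_e=s2e, weights=w, X=X
        )
        gebv = sol.total_value(val_ids, X_pred=X_val)
        debv = tr_df.loc[val_ids, data.response].to_numpy(dtype=float)
        rows.append({
            "replicate": rep,
            # checksums let paired designs verify identical splits across models
            "val_checksum": zlib.crc32(",".join(val_ids).encode()),
            "train_checksum": zlib.crc32(",".join(train_ids).encode()),
            "accuracy": accuracy(gebv, debv),
            "slope": bias_slope(gebv, debv, "debv_on_gebv"),
            "slope_rev": bias_slope(gebv, debv, "gebv_on_debv"),
            "n_train": len(train_ids),
            "n_val": len(val_ids),
            "sigma2_a": s2a,
            "sigma2_e": s2e,
            "mean_r2_train": float(tr_df.loc[train_ids, "r2"].mean()),
        })
    per_rep = pd.DataFrame(rows)
    acc = per_rep["accuracy"].to_numpy()
    defined = acc[~np.isnan(acc)]
    return ScenarioResult(
        spec=spec,
        model=model,
        per_replicate=per_rep,
        accuracy_mean=float(defined.mean()) if defined.size else float("nan"),
        accuracy_sd=float(defined.std(ddof=1)) if spec.n_replicates > 1 and defined.size > 1 else None,
        slope_mean=float(np.nanmean(per_rep["slope"])),
        slope_rev_mean=float(np.nanmean(per_rep["slope_rev"])),
        n_undefined=int(np.isnan(acc).sum()),
        mean_r2_training=float(per_rep["mean_r2_train"].mean()),
    )


# ---------------------------------------------------------------------------
# the 17-scenario suite


@dataclass
class SuiteConfig:
    pb_lines: tuple = ("L1", "L2")
    f1_line: str = "F1"
    validation_size: int = 50
    n_replicates: int = 20
    equalized_n: int | None = None   # default: min over populations (see below)
    components: object = "reml"      # "reml" or (sigma2_a, sigma2_e)
    denominator: str = "blockwise"
    models: tuple = ("gblup", "pedblup")
    seed: int = 0


def build_scenario_specs(data: WorkingSet, config: SuiteConfig) -> list[ScenarioSpec]:
    """Materialize the 17 scenario specs (groups of 3, 4, 4 and 6).

    Equalized training sizes use one N for every reduced scenario: the
    smallest population's usable training count (for the F1, its eligible
    count minus the validation holdout), so "the same number of animals from
    each population" holds across scenarios.
    """
    la, lb = config.pb_lines
    f1 = config.f1_line
    n_a, n_b = len(data.eligible(la)), len(data.eligible(lb))
    n_f1 = len(data.eligible(f1))
    v = config.validation_size
    n_eq = config.equalized_n or min(n_a - v, n_b - v, n_f1 - v)
    if n_eq < 3:
        raise DataError("equalized training size too small")
    reps = config.n_replicates
    s = config.seed
    specs = [
        # group 1: within-population
        ScenarioSpec("S01", 1, {la: "all"}, la, v, reps, "genomic_within", seed=s),
        ScenarioSpec("S02", 1, {lb: "all"}, lb, v, reps, "genomic_within", seed=s),
        ScenarioSpec("S03", 1, {f1: "all"}, f1, v, reps, "genomic_within", seed=s),
        # group 2: multi-population
        ScenarioSpec("S04", 2, {la: "all", lb: "all"}, la, v, reps, "genomic_across", seed=s),
        ScenarioSpec("S05", 2, {lb: "all", la: "all"}, lb, v, reps, "genomic_across", seed=s),
        ScenarioSpec("S06", 2, {f1: "all", la: "all", lb: "all"}, f1, v, reps, "genomic_across", seed=s),
        ScenarioSpec("S07", 2, {f1: "all", la: n_eq, lb: n_eq}, f1, v, reps, "genomic_across",
                     equalize_training_sizes=True, seed=s),
        # group 3: across-population
        ScenarioSpec("S08", 3, {la: "all"}, lb, "all", 1, "genomic_across", seed=s),
        ScenarioSpec("S09", 3, {la: n_eq}, lb, "all", reps, "genomic_across",
                     equalize_training_sizes=True, seed=s),
        ScenarioSpec("S10", 3, {lb: "all"}, la, "all", 1, "genomic_across", seed=s),
        ScenarioSpec("S11", 3, {lb: n_eq}, la, "all", reps, "genomic_across",
                     equalize_training_sizes=True, seed=s),
        # group 4: purebred -> crossbred
        ScenarioSpec("S12", 4, {la: "all", lb: "all"}, f1, "all", 1, "genomic_across", seed=s),
        ScenarioSpec("S13", 4, {la: n_eq, lb: n_eq}, f1, "all", reps, "genomic_across",
                     equalize_training_sizes=True, seed=s),
        ScenarioSpec("S14", 4, {la: "all"}, f1, "all", 1, "genomic_across", seed=s),
        ScenarioSpec("S15", 4, {la: n_eq}, f1, "all", reps, "genomic_across",
                     equalize_training_sizes=True, seed=s),
        ScenarioSpec("S16", 4, {lb: "all"}, f1, "all", 1, "genomic_across", seed=s),
        ScenarioSpec("S17", 4, {lb: n_eq}, f1, "all", reps, "genomic_across",
                     equalize_training_sizes=True, seed=s),
    ]
    return specs


PEDBLUP_SKIP_GROUPS = frozenset({3})
PEDBLUP_SKIP_REASON = (
    "across-population designs skipped for PED-BLUP: the two purebred "
    "populations are not related according to the pedigree"
)


def scenario_suite(data: WorkingSet, config: SuiteConfig):
    """Run every scenario for each requested model; return results + summary."""
    specs = build_scenario_specs(data, config)
    results = []
    for spec in specs:
        for model in config.models:
            if model == "pedblup" and spec.group in PEDBLUP_SKIP_GROUPS:
                results.append(ScenarioResult(
                    spec=spec, model=model,
                    per_replicate=pd.DataFrame(),
                    accuracy_mean=float("nan"), accuracy_sd=None,
                    slope_mean=float("nan"), slope_rev_mean=float("nan"),
                    n_undefined=0, mean_r2_training=float("nan"),
                    skipped=PEDBLUP_SKIP_REASON,
                ))
                continue
            results.append(run_scenario(
                spec, data, model=model,
                components=config.components,
                denominator=config.denominator,
            ))
    return results, summarize(results)


def summarize(results) -> pd.DataFrame:
    """Table-shaped summary: scenario, model, mean r2, N, accuracy (SD), slope."""
    rows = []
    for r in results:
        rows.append({
            "scenario": r.spec.id,
            "group": r.spec.group,
            "model": r.model,
            "matrix": "pedigree" if r.model == "pedblup" else r.spec.matrix,
            "training_lines": "+".join(
                f"{k}:{v}" for k, v in r.spec.training_lines.items()
            ),
            "validation_line": r.spec.validation_line,
            "n_replicates": r.spec.n_replicates,
            "mean_r2_training": _round(r.mean_r2_training),
            "accuracy_mean": _round(r.accuracy_mean),
            "accuracy_sd": _round(r.accuracy_sd) if r.accuracy_sd is not None else "",
            "slope_debv_on_gebv": _round(r.slope_mean),
            "slope_gebv_on_debv": _round(r.slope_rev_mean),
            "n_undefined": r.n_undefined,
            "skipped": r.skipped or "",
        })
    return pd.DataFrame(rows)


def _round(x):
    return round(float(x), 6) if x == x else float("nan")
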