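"""Synthetic two-group cohort generation.

Generates participant-level tables with the statistical structure a
case-control epigenetic-ageing analysis assumes: per-group marginal
distributions (normal or moment-matched lognormal for continuous variables,
stated category probabilities for ordinal ones), Gaussian-copula correlation
blocks with a target Spearman rank correlation, group-restricted columns,
and independently drawn outcome variables.  Also inverts the qPCR
quantification formulas to produce raw Ct-level records with configurable
measurement noise, so the quantification stage can be exercised end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .errors import ConfigurationError, InputError
from .qpcr import INPUT_DILUTION_FACTOR, CtRecord, ExpressionCtRecord

MISSING_MARKER = "NA"

_FAMILIES = ("normal", "lognormal")
_KINDS = ("continuous", "ordinal", "binary")


@dataclass(frozen=True)
class CovariateSpec:
    """Marginal distribution of one covariate in each group.

    Continuous covariates state a per-group mean and SD plus a distribution
    family; ordinal/binary covariates state per-group category probabilities
    over a shared category ladder.  ``block`` groups covariates that must be
    mutually rank-correlated (Gaussian copula).
    """

    name: str
    kind: str = "continuous"
    family: str = "normal"
    mean_group1: float | None = None
    sd_group1: float | None = None
    mean_group2: float | None = None
    sd_group2: float | None = None
    categories: tuple = ()
    probs_group1: tuple = ()
    probs_group2: tuple = ()
    block: str | None = None
    restricted_to_group1: bool = False

    def validate(self) -> None:
        if not self.name or not str(self.name).strip():
            raise ConfigurationError("covariate name must be a non-empty identifier")
        if self.kind not in _KINDS:
            raise ConfigurationError(
                f"covariate {self.name!r}: kind must be one of {_KINDS}, got {self.kind!r}"
            )
        if self.kind == "continuous":
            if self.family not in _FAMILIES:
                raise ConfigurationError(
                    f"covariate {self.name!r}: family must be one of {_FAMILIES}"
                )
            for label, m, s in (
                ("group1", self.mean_group1, self.sd_group1),
                ("group2", self.mean_group2, self.sd_group2),
            ):
                if m is None or s is None:
                    raise ConfigurationError(
                        f"covariate {self.name!r}: {label} mean/sd missing"
                    )
                if not s > 0:
                    raise ConfigurationError(
                        f"covariate {self.name!r}: {label} sd must be > 0, got {s}"
                    )
                if self.family == "lognormal" and not m > 0:
                    raise ConfigurationError(
                        f"covariate {self.name!r}: lognormal {label} mean must be > 0"
                    )
        else:
            if len(self.categories) == 0:
                raise ConfigurationError(
                    f"covariate {self.name!r}: category range is empty"
                )
            if self.kind == "binary" and len(self.categories) != 2:
                raise ConfigurationError(
                    f"covariate {self.name!r}: binary needs exactly 2 categories"
                )
            for label, probs in (
                ("probs_group1", self.probs_group1),
                ("probs_group2", self.probs_group2),
            ):
                if len(probs) != len(self.categories):
                    raise ConfigurationError(
                        f"covariate {self.name!r}: {label} length mismatch"
                    )
                if any(p < 0 for p in probs):
                    raise ConfigurationError(
                        f"covariate {self.name!r}: {label} has negative entries"
                    )
                if abs(sum(probs) - 1.0) > 1e-9:
                    raise ConfigurationError(
                        f"covariate {self.name!r}: {label} must sum to 1 "
                        f"(got {sum(probs)!r})"
                    )


@dataclass(frozen=True)
class EffectSpec:
    """Per-group marginal distribution of one outcome (dependent) variable."""

    name: str
    family: str = "lognormal"
    mean_group1: float = 1.0
    sd_group1: float = 1.0
    mean_group2: float = 1.0
    sd_group2: float = 1.0

    def validate(self) -> None:
        if not self.name or not str(self.name).strip():
            raise ConfigurationError("effect name must be a non-empty identifier")
        if self.family not in _FAMILIES:
            raise ConfigurationError(
                f"effect {self.name!r}: family must be one of {_FAMILIES}"
            )
        for label, m, s in (
            ("group1", self.mean_group1, self.sd_group1),
            ("group2", self.mean_group2, self.sd_group2),
        ):
            if not s > 0:
                raise ConfigurationError(
                    f"effect {self.name!r}: {label} sd must be > 0, got {s}"
                )
            if self.family == "lognormal" and not m > 0:
                raise ConfigurationError(
                    f"effect {self.name!r}: lognormal {label} mean must be > 0"
                )


@dataclass
class CohortConfig:
    """Full specification of a synthetic cohort."""

    n_group1: int
    n_group2: int
    covariates: list[CovariateSpec]
    effects: list[EffectSpec]
    master_seed: int = 0
    #: per-block target Spearman rank correlation (missing blocks use 0.8)
    block_correlations: dict = field(default_factory=dict)

    DEFAULT_BLOCK_RHO = 0.8

    def validate(self) -> None:
        if not (isinstance(self.n_group1, int) and self.n_group1 > 0):
            raise ConfigurationError(f"n_group1 must be a positive integer, got {self.n_group1!r}")
        if not (isinstance(self.n_group2, int) and self.n_group2 > 0):
            raise ConfigurationError(f"n_group2 must be a positive integer, got {self.n_group2!r}")
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ConfigurationError(f"duplicate covariate names: {dupes}")
        effect_names = [e.name for e in self.effects]
        if len(set(effect_names)) != len(effect_names):
            raise ConfigurationError("duplicate effect names")
        clash = set(names) & set(effect_names)
        if clash:
            raise ConfigurationError(
                f"effect names clash with covariate names: {sorted(clash)}"
            )
        for c in self.covariates:
            c.validate()
        for e in self.effects:
            e.validate()
        for blk, rho in self.block_correlations.items():
            if not -1 < rho < 1:
                raise ConfigurationError(
                    f"block_correlations[{blk!r}] must be in (-1, 1), got {rho}"
                )

    def block_rho(self, block: str) -> float:
        return float(self.block_correlations.get(block, self.DEFAULT_BLOCK_RHO))

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "n_group1": self.n_group1,
            "n_group2": self.n_group2,
            "master_seed": self.master_seed,
            "block_correlations": dict(self.block_correlations),
            "covariates": [
                {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(c).items()}
                for c in self.covariates
            ],
            "effects": [asdict(e) for e in self.effects],
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        covs = [
            CovariateSpec(
                **{
                    k: (tuple(v) if isinstance(v, list) else v)
                    for k, v in c.items()
                }
            )
            for c in d.get("covariates", [])
        ]
        effs = [EffectSpec(**e) for e in d.get("effects", [])]
        return cls(
            n_group1=d["n_group1"],
            n_group2=d["n_group2"],
            covariates=covs,
            effects=effs,
            master_seed=d.get("master_seed", 0),
            block_correlations=dict(d.get("block_correlations", {})),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class CohortTable:
    """A participant-level table plus its column schema.

    ``data`` has one row per participant: ``participant_id``, ``group``
    (1 = exposed, 0 = control), covariates, then outcome columns.
    Group-restricted columns carry NaN outside their group.
    """

    data: pd.DataFrame
    ordinal: tuple = ()
    continuous: tuple = ()
    dependent: tuple = ()
    restricted: tuple = ()
    group_col: str = "group"
    id_col: str = "participant_id"

    @property
    def covariate_names(self) -> tuple:
        return tuple(self.ordinal) + tuple(self.continuous)

    def group_mask(self, group: int) -> np.ndarray:
        return (self.data[self.group_col] == group).to_numpy()

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, na_rep=MISSING_MARKER)

    @classmethod
    def from_csv(cls, path, *, ordinal=None, continuous=None, dependent=None,
                 restricted=None, group_col="group", id_col="participant_id"):
        """Read a cohort CSV; infer the schema when not stated.

        Inference: columns with <= 6 distinct integer values are ordinal;
        columns named like the default outcome roster (suffix ``_methylation``
        or ``_expression``) are outcomes; columns with missing values only in
        one group are marked restricted.
        """
        df = pd.read_csv(path, na_values=[MISSING_MARKER])
        value_cols = [c for c in df.columns if c not in (group_col, id_col)]
        if dependent is None:
            dependent = tuple(
                c for c in value_cols
                if c.endswith("_methylation") or c.endswith("_expression")
            )
        covs = [c for c in value_cols if c not in dependent]
        if ordinal is None:
            ordinal = tuple(
                c for c in covs
                if df[c].dropna().nunique() <= 6
                and np.allclose(df[c].dropna() % 1, 0)
            )
        if continuous is None:
            continuous = tuple(c for c in covs if c not in ordinal)
        if restricted is None:
            restricted = tuple(c for c in covs if df[c].isna().any())
        return cls(
            data=df,
            ordinal=tuple(ordinal),
            continuous=tuple(continuous),
            dependent=tuple(dependent),
            restricted=tuple(restricted),
            group_col=group_col,
            id_col=id_col,
        )


# ---------------------------------------------------------------------------
# marginal transforms


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched (mu, sigma) of a lognormal with the given mean and SD."""
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _continuous_from_z(z, family, mean, sd):
    if family == "normal":
        return mean + sd * z
    mu, sigma = _lognormal_params(mean, sd)
    return np.exp(mu + sigma * z)


def _ordinal_from_z(z, categories, probs):
    cum = np.cumsum(probs)
    cum[-1] = 1.0  # guard against rounding past 1
    u = sps.norm.cdf(z)
    idx = np.searchsorted(cum, u, side="left")
    return np.asarray(categories)[np.clip(idx, 0, len(categories) - 1)]


def _latent_rho(rank_rho: float) -> float:
    """Latent Gaussian correlation yielding a target Spearman rho."""
    return 2.0 * math.sin(math.pi * rank_rho / 6.0)


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(config: CohortConfig, seed: int | None = None) -> CohortTable:
    """Draw one cohort.  Deterministic given ``(config, seed)``.

    Covariates sharing a correlation block are drawn from an exchangeable
    Gaussian copula whose latent correlation is chosen so continuous block
    members reach the block's target Spearman rank correlation; all other
    variables, and all outcome variables, are mutually independent.
    """
    config.validate()
    if seed is None:
        seed = config.master_seed
    rng = np.random.default_rng(seed)
    n1, n2 = config.n_group1, config.n_group2
    n = n1 + n2

    # latent standard-normal draws, correlated within blocks
    z = {}
    blocks: dict[str, list[str]] = {}
    for c in config.covariates:
        if c.block is not None:
            blocks.setdefault(c.block, []).append(c.name)
    blocked = {name for members in blocks.values() for name in members}
    for blk, members in sorted(blocks.items()):
        k = len(members)
        rho = _latent_rho(config.block_rho(blk))
        cov = np.full((k, k), rho)
        np.fill_diagonal(cov, 1.0)
        draws = rng.multivariate_normal(np.zeros(k), cov, size=n, method="cholesky")
        for j, name in enumerate(members):
            z[name] = draws[:, j]
    for c in config.covariates:
        if c.name not in blocked:
            z[c.name] = rng.standard_normal(n)

    g1 = np.arange(n) < n1
    columns: dict[str, np.ndarray] = {
        "participant_id": np.array([f"P{i + 1:03d}" for i in range(n)]),
        "group": np.where(g1, 1, 0),
    }
    ordinal, continuous, restricted = [], [], []
    for c in config.covariates:
        zc = z[c.name]
        if c.kind == "continuous":
            vals = np.empty(n)
            vals[g1] = _continuous_from_z(zc[g1], c.family, c.mean_group1, c.sd_group1)
            vals[~g1] = _continuous_from_z(zc[~g1], c.family, c.mean_group2, c.sd_group2)
            continuous.append(c.name)
        else:
            vals = np.empty(n)
            vals[g1] = _ordinal_from_z(zc[g1], c.categories, c.probs_group1)
            vals[~g1] = _ordinal_from_z(zc[~g1], c.categories, c.probs_group2)
            ordinal.append(c.name)
        if c.restricted_to_group1:
            vals = vals.astype(float)
            vals[~g1] = np.nan
            restricted.append(c.name)
        columns[c.name] = vals

    dependent = []
    for e in config.effects:
        ze = rng.standard_normal(n)
        vals = np.empty(n)
        vals[g1] = _continuous_from_z(ze[g1], e.family, e.mean_group1, e.sd_group1)
        vals[~g1] = _continuous_from_z(ze[~g1], e.family, e.mean_group2, e.sd_group2)
        columns[e.name] = vals
        dependent.append(e.name)

    return CohortTable(
        data=pd.DataFrame(columns),
        ordinal=tuple(ordinal),
        continuous=tuple(continuous),
        dependent=tuple(dependent),
        restricted=tuple(restricted),
    )


# ---------------------------------------------------------------------------
# Ct-level simulation (inverse of the quantification formulas)


def simulate_medip_ct(
    true_recovery_pct: float,
    ct_input: float = 24.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    *,
    sample_id: str = "S1",
    locus: str = "global",
) -> CtRecord:
    """Invert the percent-recovery formula to a (CtIN, CtIP) pair.

    CtIP = CtIN - 3.32 - log2(recovery/100), plus zero-mean Gaussian Ct
    noise of ``noise_sd`` cycles on the IP measurement.  With zero noise the
    pair round-trips through :func:`epicohort.qpcr.percent_recovery` exactly.
    """
    if not true_recovery_pct > 0:
        raise InputError(f"true_recovery_pct must be > 0, got {true_recovery_pct}")
    if not ct_input > 0:
        raise InputError(f"ct_input must be > 0, got {ct_input}")
    if noise_sd < 0:
        raise InputError(f"noise_sd must be >= 0, got {noise_sd}")
    ct_ip = ct_input - INPUT_DILUTION_FACTOR - math.log2(true_recovery_pct / 100.0)
    if noise_sd > 0:
        ct_ip += float(np.random.default_rng(seed).normal(0.0, noise_sd))
    return CtRecord(sample_id=sample_id, ct_in=ct_input, ct_ip=ct_ip, locus=locus)


def simulate_expression_ct(
    true_rq: float,
    ct_reference: float = 18.0,
    control_mean_dct: float = 6.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    *,
    sample_id: str = "S1",
    gene: str = "DNMT1",
) -> ExpressionCtRecord:
    """Invert the ddCt formula to a (Ct_target, Ct_reference) pair.

    Ct_target = Ct_reference + control-mean dCt - log2(RQ), plus Gaussian Ct
    noise on the target measurement; a noiseless round trip through
    :func:`epicohort.qpcr.relative_expression` (with controls at the stated
    mean dCt) recovers ``true_rq`` exactly.
    """
    if not true_rq > 0:
        raise InputError(f"true_rq must be > 0, got {true_rq}")
    ct_target = ct_reference + control_mean_dct - math.log2(true_rq)
    if noise_sd < 0:
        raise InputError(f"noise_sd must be >= 0, got {noise_sd}")
    if noise_sd > 0:
        ct_target += float(np.random.default_rng(seed).normal(0.0, noise_sd))
    return ExpressionCtRecord(
        sample_id=sample_id, gene=gene, ct_target=ct_target, ct_reference=ct_reference
    )
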