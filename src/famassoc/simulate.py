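"""Family-structured phenotype simulation.

Each marker j gets its own response vector drawn from the generating mixed
model

    y_j = delta_j * 1 + mu_j + eps_j,
    mu_j  ~ N(0, sigma2_mu * K),      eps_j ~ N(0, sigma2_eps * I),

with K the block-exchangeable family relationship matrix.  ``delta_j`` is
``effect_delta`` for the ``m_causal`` causal markers (drawn without
replacement by the config seed) and 0 otherwise, so under the alternative
the response mean is shifted away from zero.  Markers are mutually
independent given K.

``mode="covariate"`` instead embeds the signal in the coefficient of a
continuous exposure inside a fixed-effect design emulating a
sibship-cohort analysis (age, sex, site and four orthonormal PC-like
columns as nuisance covariates); the tested coefficient is the exposure's.
"""

from __future__ import annotations

import dataclasses
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .kinship import KinshipMatrix, exchangeable_family_matrix

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_dataset",
    "emulate_goldn_covariates",
]

MODES = ("mean_shift", "covariate")

COVARIATE_COLUMNS = (
    "intercept",
    "exposure",
    "age",
    "sex",
    "site",
    "pc1",
    "pc2",
    "pc3",
    "pc4",
)

# fixed nuisance coefficients used in covariate mode (intercept, age, sex,
# site, pc1..pc4); the exposure coefficient carries the per-marker signal
_NUISANCE_BETA = np.array([0.0, 0.01, 0.3, 0.2, 0.5, -0.5, 0.5, -0.5])


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated study.

    Defaults reproduce the simulation design: 200 sibship families, 1000
    markers of which 10 carry a mean shift, unit variance components, and
    full-sib within-family relationship 0.5.
    """

    n_families: int = 200
    family_size: int = 5
    m_markers: int = 1000
    m_causal: int = 10
    effect_delta: float = 0.5
    sigma2_mu: float = 1.0
    sigma2_eps: float = 1.0
    within_value: float = 0.5
    mode: str = "mean_shift"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.family_size < 1:
            raise ValueError("n_families and family_size must be positive")
        if self.m_causal > self.m_markers:
            raise ValueError("m_causal cannot exceed m_markers")
        if self.m_causal < 0:
            raise ValueError("m_causal must be nonnegative")
        if self.sigma2_mu < 0 or self.sigma2_eps <= 0:
            raise ValueError("require sigma2_mu >= 0 and sigma2_eps > 0")
        if not 0.0 <= self.within_value < 1.0:
            raise ValueError("within_value must be in [0, 1)")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")

    @property
    def n(self) -> int:
        return self.n_families * self.family_size

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(
                f"unknown config keys: {sorted(unknown)}; known keys: {sorted(known)}"
            )
        return cls(**d)


@dataclass(frozen=True)
class SimulatedDataset:
    """Responses, design, truth labels and kinship for one simulated study."""

    individual_ids: tuple[str, ...]
    family_ids: tuple[str, ...]  # family label per individual, aligned
    marker_ids: tuple[str, ...]
    responses: np.ndarray = field(repr=False)  # n x m
    covariates: np.ndarray = field(repr=False)  # n x p
    covariate_names: tuple[str, ...]
    truth: np.ndarray = field(repr=False)  # bool, length m
    kinship: KinshipMatrix = field(repr=False)
    config: SimulationConfig

    @property
    def n(self) -> int:
        return len(self.individual_ids)

    @property
    def m(self) -> int:
        return len(self.marker_ids)

    @property
    def tested_coef_index(self) -> int:
        """Column of the tested coefficient: intercept (mean-shift mode) or
        the exposure (covariate mode)."""
        return 0 if self.config.mode == "mean_shift" else 1

    @property
    def families(self) -> "OrderedDict[str, list[str]]":
        fams: "OrderedDict[str, list[str]]" = OrderedDict()
        for iid, fid in zip(self.individual_ids, self.family_ids):
            fams.setdefault(fid, []).append(iid)
        return fams

    @property
    def causal_ids(self) -> frozenset[str]:
        return frozenset(np.array(self.marker_ids)[self.truth])

    # -- text serialization ----------------------------------------------
    def write(self, outdir: str | Path) -> None:
        """Write phenotype/covariate/truth/kinship TSVs plus a config sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        idx = pd.Index(list(self.individual_ids), name="individual_id")
        pd.DataFrame(self.responses, index=idx, columns=list(self.marker_ids)).to_csv(
            outdir / "phenotypes.tsv", sep="\t", float_format="%.12g"
        )
        cov = pd.DataFrame(
            self.covariates, index=idx, columns=list(self.covariate_names)
        )
        cov.insert(0, "family_id", list(self.family_ids))
        cov.to_csv(outdir / "covariates.tsv", sep="\t", float_format="%.12g")
        pd.DataFrame(
            {"marker_id": list(self.marker_ids), "causal": self.truth.astype(int)}
        ).to_csv(outdir / "truth.tsv", sep="\t", index=False)
        self.kinship.to_tsv(outdir / "kinship.tsv")
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(self.config.to_dict(), fh, sort_keys=True)

    @classmethod
    def read(cls, indir: str | Path) -> "SimulatedDataset":
        indir = Path(indir)
        with open(indir / "config.yaml") as fh:
            config = SimulationConfig.from_dict(yaml.safe_load(fh))
        phen = pd.read_csv(indir / "phenotypes.tsv", sep="\t", index_col=0)
        cov = pd.read_csv(indir / "covariates.tsv", sep="\t", index_col=0)
        truth = pd.read_csv(indir / "truth.tsv", sep="\t")
        kin = KinshipMatrix.read_tsv(indir / "kinship.tsv")
        family_ids = tuple(cov.pop("family_id").astype(str))
        return cls(
            individual_ids=tuple(phen.index.astype(str)),
            family_ids=family_ids,
            marker_ids=tuple(phen.columns.astype(str)),
            responses=phen.to_numpy(dtype=float),
            covariates=cov.to_numpy(dtype=float),
            covariate_names=tuple(cov.columns),
            truth=truth["causal"].to_numpy(dtype=bool),
            kinship=kin,
            config=config,
        )


def _goldn_design(n: int, rng: np.random.Generator) -> np.ndarray:
    """n x 9 design: intercept, exposure, age, sex, site, 4 PC-like columns."""
    if n < len(COVARIATE_COLUMNS):
        raise ValueError(
            f"need n >= {len(COVARIATE_COLUMNS)} rows for a full-rank design, got {n}"
        )
    exposure = rng.standard_normal(n)
    age = rng.integers(20, 81, size=n).astype(float)
    # balanced binary covariates so the design never degenerates at small n
    sex = rng.permutation(np.arange(n) % 2).astype(float)
    site = rng.permutation(np.arange(n) % 2).astype(float)
    pcs = rng.standard_normal((n, 4))
    pcs -= pcs.mean(axis=0)  # mean-zero, so Q spans a mean-zero subspace
    q, _ = np.linalg.qr(pcs)
    X = np.column_stack([np.ones(n), exposure, age, sex, site, q])
    return X


def emulate_goldn_covariates(n: int, seed: int) -> np.ndarray:
    """Fixed-effect design emulating a sibship-cohort covariate structure.

    Columns: intercept, continuous exposure (standard normal), age (uniform
    integers 20-80), balanced binary sex and study site, and four mutually
    orthonormal mean-zero principal-component-like columns.  Full column
    rank for any ``n >= 9``.
    """
    return _goldn_design(n, np.random.default_rng(seed))


def simulate_dataset(
    config: SimulationConfig, kinship: Optional[KinshipMatrix] = None
) -> SimulatedDataset:
    """Draw a :class:`SimulatedDataset` under the generating mixed model.

    With the default (block-exchangeable) kinship the family random effect
    is composed from a shared family draw and an individual draw,
    ``mu = sqrt(w)*a_family + sqrt(1-w)*b_individual``, which has exactly the
    exchangeable covariance; a user-supplied ``kinship`` is handled through
    its symmetric eigendecomposition and must be PSD.
    Regenerating with an identical config is bit-identical.
    """
    n, m = config.n, config.m_markers
    if kinship is None:
        K = exchangeable_family_matrix(
            config.n_families, config.family_size, config.within_value
        )
        transform = None
    else:
        K = kinship
        if len(K) != n:
            raise ValueError(
                f"supplied kinship has {len(K)} ids but config implies n={n}"
            )
        w, U = np.linalg.eigh(K.values)
        if w[0] < -1e-8:
            raise ValueError(
                f"supplied kinship is not positive semidefinite "
                f"(smallest eigenvalue {w[0]:.3e})"
            )
        transform = U * np.sqrt(np.clip(w, 0.0, None))

    family_of = tuple(iid.rsplit("-", 1)[0] for iid in K.ids)
    rng = np.random.default_rng(config.seed)

    truth = np.zeros(m, dtype=bool)
    if config.m_causal:
        causal = rng.choice(m, size=config.m_causal, replace=False)
        truth[causal] = True

    if transform is None:
        fam_index = np.repeat(np.arange(config.n_families), config.family_size)
        shared = rng.standard_normal((config.n_families, m))
        indiv = rng.standard_normal((n, m))
        mu = np.sqrt(config.sigma2_mu) * (
            np.sqrt(config.within_value) * shared[fam_index]
            + np.sqrt(1.0 - config.within_value) * indiv
        )
    else:
        mu = np.sqrt(config.sigma2_mu) * (transform @ rng.standard_normal((n, m)))
    eps = np.sqrt(config.sigma2_eps) * rng.standard_normal((n, m))
    Y = mu + eps

    if config.mode == "mean_shift":
        Y[:, truth] += config.effect_delta
        X = np.ones((n, 1))
        names: tuple[str, ...] = ("intercept",)
    else:
        X = _goldn_design(n, rng)
        names = COVARIATE_COLUMNS
        nuisance = np.delete(X, 1, axis=1) @ _NUISANCE_BETA
        Y += nuisance[:, None]
        Y[:, truth] += config.effect_delta * X[:, 1:2]

    marker_ids = tuple(f"M{j:05d}" for j in range(1, m + 1))
    return SimulatedDataset(
        individual_ids=K.ids,
        family_ids=family_of,
        marker_ids=marker_ids,
        responses=Y,
        covariates=X,
        covariate_names=names,
        truth=truth,
        kinship=K,
        config=config,
    )
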