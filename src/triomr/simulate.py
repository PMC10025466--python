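"""Trio-population simulators for assortative mating and stratification.

Two generative scenarios produce father–mother–offspring trios at two unlinked
diallelic loci, G (the instrument, alleles A/a) and H (a heritable confounder,
alleles B/b):

* ``sim1-assortative`` — a single random-mating population in which a
  proportion ``p_assort`` of couples are instead formed by rank-matching
  mothers and fathers on the exposure X (positive assortative mating).
* ``sim2-stratified`` — two random-mating subpopulations with different
  allele frequencies, pooled and analysed as one sample.

Both mechanisms induce an association between the unlinked loci G and H
(gametic-phase disequilibrium) and hence between the instrument and the
confounder, which is exactly the condition under which conventional
Mendelian-randomization estimates go wrong.

The exposure and outcome follow linear models with additive and dominance
genotype codings::

    X = b1 + bGAX*fA(G) + bGDX*fD(G) + bHAX*fA(H) + bHDX*fD(H) + bUX*U + eps_X
    Y = b2 + bXY*X + bHAY*fA(H) + bHDY*fD(H) + bUY*U + eps_Y

where U is a non-genetic confounder and eps_* are Gaussian noise.  The default
parameter set (``default_params``) is the dominance-driven configuration used
throughout the package's reference experiments: allele frequencies 0.1, no
additive genetic effects, dominance effects of 1 on every affected trait,
confounder effects of 1, and noise/confounder variances of 0.1.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .genetics import (
    additive_code,
    dominance_code,
    genotype_label,
    parse_genotype_label,
    sample_genotype_hwe,
    transmit,
)

__all__ = [
    "SimParams",
    "Individual",
    "Trio",
    "TrioDataset",
    "default_params",
    "phenotype_x",
    "phenotype_y",
    "simulate_parent_pool",
    "assortative_pairing",
    "make_offspring",
    "simulate_assortative",
    "simulate_stratified",
    "simulate_scenario",
    "SCENARIOS",
    "CSV_COLUMNS",
]

SCENARIOS = ("sim1-assortative", "sim2-stratified")

CSV_COLUMNS = [
    "family_id", "subpop",
    "Gm", "Gf", "G", "Hm", "Hf", "H",
    "Xm", "Xf", "X", "Ym", "Yf", "Y",
]


@dataclass(frozen=True)
class SimParams:
    """All data-generating parameters for one trio population.

    Variances are variances (``N(0, 0.1)`` means variance 0.1, standard
    deviation sqrt(0.1)).  ``n_trios`` is the number of families generated for
    this (sub)population.  ``rho_u_parent_offspring`` sets the correlation of
    the offspring's confounder with each parent's (0 means the confounder is
    drawn fresh, i.e. entirely non-transmissible).
    """

    freq_A: float = 0.1
    freq_B: float = 0.1
    beta1: float = 0.0
    beta2: float = 0.0
    beta_GA_X: float = 0.0
    beta_GD_X: float = 1.0
    beta_HA_X: float = 0.0
    beta_HD_X: float = 1.0
    beta_HA_Y: float = 0.0
    beta_HD_Y: float = 1.0
    beta_U_X: float = 1.0
    beta_U_Y: float = 1.0
    beta_XY: float = 1.0
    var_U: float = 0.1
    var_eps_X: float = 0.1
    var_eps_Y: float = 0.1
    p_assort: float = 0.0
    rho_u_parent_offspring: float = 0.0
    n_trios: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("freq_A", "freq_B", "p_assort"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("var_U", "var_eps_X", "var_eps_Y"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be non-negative")
        r = self.rho_u_parent_offspring
        if not 2.0 * r * r <= 1.0:
            raise ValueError(
                "rho_u_parent_offspring must satisfy |rho| <= 1/sqrt(2) "
                "(the offspring confounder correlates with both parents')")
        if self.n_trios < 1:
            raise ValueError("n_trios must be at least 1")

    def replace(self, **changes) -> "SimParams":
        return dataclasses.replace(self, **changes)


def default_params(**overrides) -> SimParams:
    """The package's reference parameter set (see module docstring)."""
    return SimParams(**overrides)


@dataclass
class Individual:
    """One person: genotypes at G and H, confounder, exposure, outcome."""

    g: int
    h: int
    u: float
    x: float
    y: float


@dataclass
class Trio:
    mother: Individual
    father: Individual
    offspring: Individual
    subpopulation: int = 0
    family_id: int = 0


class Cohort:
    """Array-backed collection of individuals (one generation)."""

    __slots__ = ("g", "h", "u", "x", "y")

    def __init__(self, g, h, u, x, y):
        self.g, self.h, self.u, self.x, self.y = g, h, u, x, y

    def __len__(self) -> int:
        return len(self.g)

    def take(self, idx) -> "Cohort":
        return Cohort(self.g[idx], self.h[idx], self.u[idx], self.x[idx], self.y[idx])

    def individual(self, i: int) -> Individual:
        return Individual(int(self.g[i]), int(self.h[i]),
                          float(self.u[i]), float(self.x[i]), float(self.y[i]))


def phenotype_x(g, h, u, eps, params: SimParams):
    """Exposure model: intercept + G and H codings + confounder + noise."""
    return (params.beta1
            + params.beta_GA_X * additive_code(g)
            + params.beta_GD_X * dominance_code(g)
            + params.beta_HA_X * additive_code(h)
            + params.beta_HD_X * dominance_code(h)
            + params.beta_U_X * np.asarray(u)
            + np.asarray(eps))


def phenotype_y(x, h, u, eps, params: SimParams):
    """Outcome model: intercept + causal X effect + H codings + confounder + noise."""
    return (params.beta2
            + params.beta_XY * np.asarray(x)
            + params.beta_HA_Y * additive_code(h)
            + params.beta_HD_Y * dominance_code(h)
            + params.beta_U_Y * np.asarray(u)
            + np.asarray(eps))


def simulate_parent_pool(n: int, params: SimParams, rng: np.random.Generator) -> Cohort:
    """n founders: genotypes under Hardy–Weinberg, then phenotypes."""
    if n < 1:
        raise ValueError("pool size must be at least 1")
    g = sample_genotype_hwe(params.freq_A, rng, size=n)
    h = sample_genotype_hwe(params.freq_B, rng, size=n)
    u = rng.normal(0.0, np.sqrt(params.var_U), size=n)
    x = phenotype_x(g, h, u, rng.normal(0.0, np.sqrt(params.var_eps_X), size=n), params)
    y = phenotype_y(x, h, u, rng.normal(0.0, np.sqrt(params.var_eps_Y), size=n), params)
    return Cohort(g, h, u, x, y)


def assortative_pairing(x_mothers, x_fathers, p_assort: float,
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Pair two parent pools, a fraction of them by exposure rank.

    round(p_assort * n) mothers and as many fathers are selected uniformly at
    random; each selected set is sorted by exposure and paired rank-to-rank.
    The unselected remainder is paired uniformly at random.  Returns index
    arrays ``(mother_idx, father_idx)``: couple ``i`` is
    ``(mothers[mother_idx[i]], fathers[father_idx[i]])``, and every individual
    appears in exactly one couple.
    """
    x_mothers = np.asarray(x_mothers, dtype=float)
    x_fathers = np.asarray(x_fathers, dtype=float)
    n = len(x_mothers)
    if len(x_fathers) != n:
        raise ValueError("mother and father pools must have equal size")
    if not 0.0 <= p_assort <= 1.0:
        raise ValueError("p_assort must be in [0, 1]")
    k = round(p_assort * n)

    sel_m = rng.choice(n, size=k, replace=False)
    sel_f = rng.choice(n, size=k, replace=False)
    sel_m = sel_m[np.argsort(x_mothers[sel_m], kind="stable")]
    sel_f = sel_f[np.argsort(x_fathers[sel_f], kind="stable")]

    rest_m = np.setdiff1d(np.arange(n), sel_m, assume_unique=False)
    rest_f = np.setdiff1d(np.arange(n), sel_f, assume_unique=False)
    rest_m = rng.permutation(rest_m)
    rest_f = rng.permutation(rest_f)

    return np.concatenate([sel_m, rest_m]), np.concatenate([sel_f, rest_f])


def make_offspring(mothers: Cohort, fathers: Cohort, params: SimParams,
                   rng: np.random.Generator) -> Cohort:
    """One offspring per couple (pools must already be couple-aligned).

    Genotypes are Mendelian transmissions; the confounder is drawn with the
    configured parent–offspring correlation (fresh and independent at the
    default 0); phenotypes follow the same models as for the parents.
    """
    n = len(mothers)
    g = transmit(mothers.g, fathers.g, rng)
    h = transmit(mothers.h, fathers.h, rng)
    rho = params.rho_u_parent_offspring
    z = rng.normal(0.0, 1.0, size=n)
    # Corr(u_offspring, u_parent) = rho for each parent and Var(u) = var_U,
    # exact when the two parental confounders are uncorrelated.
    u = rho * (mothers.u + fathers.u) + np.sqrt(params.var_U * (1.0 - 2.0 * rho * rho)) * z
    x = phenotype_x(g, h, u, rng.normal(0.0, np.sqrt(params.var_eps_X), size=n), params)
    y = phenotype_y(x, h, u, rng.normal(0.0, np.sqrt(params.var_eps_Y), size=n), params)
    return Cohort(g, h, u, x, y)


@dataclass
class TrioDataset:
    """A table of trio families plus the parameters that generated it.

    ``df`` has one row per family with integer dosage columns (Gm, Gf, G, Hm,
    Hf, H), phenotype columns for all three members, subpopulation labels and
    unique family ids.  The confounder columns (Um, Uf, U) are retained for
    diagnostics when the data were simulated but are never serialized — the
    confounder is unmeasurable by construction.
    """

    df: pd.DataFrame
    params: tuple[SimParams, ...] = field(default_factory=tuple)

    @property
    def n_trios(self) -> int:
        return len(self.df)

    def __len__(self) -> int:
        return len(self.df)

    def iter_trios(self) -> Iterator[Trio]:
        for row in self.df.itertuples(index=False):
            u = {"Um": getattr(row, "Um", np.nan),
                 "Uf": getattr(row, "Uf", np.nan),
                 "U": getattr(row, "U", np.nan)}
            yield Trio(
                mother=Individual(int(row.Gm), int(row.Hm), float(u["Um"]),
                                  float(row.Xm), float(row.Ym)),
                father=Individual(int(row.Gf), int(row.Hf), float(u["Uf"]),
                                  float(row.Xf), float(row.Yf)),
                offspring=Individual(int(row.G), int(row.H), float(u["U"]),
                                     float(row.X), float(row.Y)),
                subpopulation=int(row.subpop),
                family_id=int(row.family_id),
            )

    def to_csv(self, path) -> None:
        """Write the canonical trio table (genotypes as text labels)."""
        out = self.df[CSV_COLUMNS].copy()
        for col in ("Gm", "Gf", "G"):
            out[col] = [genotype_label(d, "G") for d in out[col]]
        for col in ("Hm", "Hf", "H"):
            out[col] = [genotype_label(d, "H") for d in out[col]]
        text = out.to_csv(index=False, lineterminator="\n")
        if isinstance(path, io.TextIOBase):
            path.write(text)
        else:
            with open(path, "w", encoding="utf-8", newline="") as fh:
                fh.write(text)

    @classmethod
    def from_csv(cls, path, validate: bool = True) -> "TrioDataset":
        """Read a trio table, decoding genotype labels and checking pedigrees."""
        df = pd.read_csv(path, float_precision="round_trip")
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise TrioDataError(f"trio table is missing columns: {missing}")
        df = df[CSV_COLUMNS].copy()
        for col in ("Gm", "Gf", "G", "Hm", "Hf", "H"):
            try:
                df[col] = [parse_genotype_label(str(v)) for v in df[col]]
            except ValueError as exc:
                raise TrioDataError(f"column {col}: {exc}") from exc
        df["family_id"] = df["family_id"].astype(np.int64)
        df["subpop"] = df["subpop"].astype(np.int64)
        ds = cls(df=df)
        if validate:
            ds.validate()
        return ds

    def validate(self) -> None:
        """Check family-id uniqueness and Mendelian consistency at both loci."""
        fid = self.df["family_id"].to_numpy()
        if len(np.unique(fid)) != len(fid):
            raise TrioDataError("family_id values are not unique")
        for locus, (cm, cf, co) in {"G": ("Gm", "Gf", "G"),
                                    "H": ("Hm", "Hf", "H")}.items():
            gm = self.df[cm].to_numpy()
            gf = self.df[cf].to_numpy()
            g = self.df[co].to_numpy()
            lo = (gm == 2).astype(int) + (gf == 2).astype(int)
            hi = (gm >= 1).astype(int) + (gf >= 1).astype(int)
            bad = np.nonzero((g < lo) | (g > hi))[0]
            if bad.size:
                i = int(bad[0])
                raise TrioDataError(
                    f"family {int(fid[i])}: offspring genotype dosage {int(g[i])} "
                    f"at locus {locus} is Mendelian-inconsistent with parental "
                    f"dosages {int(gm[i])}/{int(gf[i])}"
                )


class TrioDataError(ValueError):
    """Malformed or pedigree-inconsistent trio table."""


def _assemble(mothers: Cohort, fathers: Cohort, offspring: Cohort,
              subpop: int, fid0: int) -> pd.DataFrame:
    n = len(offspring)
    return pd.DataFrame({
        "family_id": np.arange(fid0, fid0 + n, dtype=np.int64),
        "subpop": np.full(n, subpop, dtype=np.int64),
        "Gm": mothers.g, "Gf": fathers.g, "G": offspring.g,
        "Hm": mothers.h, "Hf": fathers.h, "H": offspring.h,
        "Xm": mothers.x, "Xf": fathers.x, "X": offspring.x,
        "Ym": mothers.y, "Yf": fathers.y, "Y": offspring.y,
        "Um": mothers.u, "Uf": fathers.u, "U": offspring.u,
    })


def _simulate_population(params: SimParams, rng: np.random.Generator,
                         subpop: int, fid0: int) -> pd.DataFrame:
    n = params.n_trios
    mothers = simulate_parent_pool(n, params, rng)
    fathers = simulate_parent_pool(n, params, rng)
    m_idx, f_idx = assortative_pairing(mothers.x, fathers.x, params.p_assort, rng)
    mothers = mothers.take(m_idx)
    fathers = fathers.take(f_idx)
    offspring = make_offspring(mothers, fathers, params, rng)
    return _assemble(mothers, fathers, offspring, subpop, fid0)


def simulate_assortative(params: SimParams,
                         rng: np.random.Generator | None = None) -> TrioDataset:
    """Simulate one population of trios with partial assortative mating.

    Deterministic given ``params.seed`` (unless an external ``rng`` is
    supplied, in which case the caller owns reproducibility).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    return TrioDataset(df=_simulate_population(params, rng, 0, 0), params=(params,))


def simulate_stratified(params_pop1: SimParams, params_pop2: SimParams) -> TrioDataset:
    """Pool two independent random-mating subpopulations into one sample.

    Both parameter sets must have ``p_assort`` = 0: stratification is studied
    in isolation from assortative mating.  Subpopulations are labelled 0 and 1;
    the first set's seed drives both (independent sub-streams).
    """
    for i, p in enumerate((params_pop1, params_pop2)):
        if p.p_assort != 0.0:
            raise ValueError(
                f"stratified scenario requires p_assort=0 (subpopulation {i} "
                f"has p_assort={p.p_assort})")
    rng1, rng2 = [np.random.default_rng(s)
                  for s in np.random.SeedSequence(params_pop1.seed).spawn(2)]
    df1 = _simulate_population(params_pop1, rng1, 0, 0)
    df2 = _simulate_population(params_pop2, rng2, 1, params_pop1.n_trios)
    df = pd.concat([df1, df2], ignore_index=True)
    return TrioDataset(df=df, params=(params_pop1, params_pop2))


def simulate_scenario(scenario: str, *, seed: int, beta_xy: float = 1.0,
                      p_assort: float = 0.8, freq2: float = 0.5,
                      n_trios: int | None = None, **overrides) -> TrioDataset:
    """Simulate one dataset from a named scenario preset.

    ``sim1-assortative``: one population (default 1,000 trios) with assortment
    proportion ``p_assort``.  ``sim2-stratified``: two pooled random-mating
    subpopulations (default 500 trios each) with subpopulation-1 allele
    frequencies 0.1 and subpopulation-2 frequencies ``freq2`` at both loci.
    Remaining keyword overrides are passed to :class:`SimParams`.
    """
    if scenario == "sim1-assortative":
        n = 1000 if n_trios is None else n_trios
        params = default_params(p_assort=p_assort, beta_XY=beta_xy,
                                n_trios=n, seed=seed, **overrides)
        return simulate_assortative(params)
    if scenario == "sim2-stratified":
        n = 500 if n_trios is None else n_trios
        p1 = default_params(p_assort=0.0, beta_XY=beta_xy, n_trios=n,
                            seed=seed, **overrides)
        p2 = p1.replace(freq_A=freq2, freq_B=freq2)
        return simulate_stratified(p1, p2)
    raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
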