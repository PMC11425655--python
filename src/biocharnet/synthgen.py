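"""Seeded generators for synthetic community, environment and adsorption data.

The community generator emulates a two-treatment soil incubation (no-biochar
``NB`` vs biochar ``AB``, nine replicates each) sequenced at amplicon depth:
OTU counts arise from latent module activities through a log-linear model and
multinomial sampling, one module is coupled (negatively, by default) to a
p-coumaric-acid trait, and two designated hub genera carry a dedicated hub
factor that also feeds the trait.

Geometry of the latent space
----------------------------
Module activities, the hub factor and the trait residual are drawn as an
orthonormal in-sample basis (orthogonal to the intercept and to the
treatment contrast), and each OTU's idiosyncratic noise is orthogonalised
against every trait-coupled direction.  Planted correlations are therefore
realised exactly in the sample rather than only in expectation: module
membership, module-trait coupling and the hub/non-hub margin survive at the
small sample size (n = 18) that the incubation design dictates, while
OTU-OTU clustering noise remains realistic.  See docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .adsorb import (
    KINETIC_MODELS,
    ISOTHERM_MODELS,
    AdsorptionSeries,
    elovich_curve,
    freundlich_curve,
    idm_curve,
    langmuir_curve,
    pke_curve,
)
from .community import OTUTable


class ConfigError(ValueError):
    """Raised for invalid generator configuration."""


def _load_genus_pool() -> pd.DataFrame:
    path = resources.files("biocharnet").joinpath("data/genus_pool.txt")
    with path.open() as fh:
        rows = [
            line.rstrip("\n").split("\t")
            for line in fh
            if line.strip() and not line.startswith("#")
        ]
    return pd.DataFrame(rows, columns=["phylum", "class", "order", "family", "genus"])


def _lineage(row: pd.Series) -> str:
    return (
        f"k__Bacteria;p__{row['phylum']};c__{row['class']};o__{row['order']};"
        f"f__{row['family']};g__{row['genus']};s__"
    )


# ---------------------------------------------------------------------------
# community

@dataclass
class CommunityConfig:
    """Parameters of the synthetic community.

    The defaults reproduce the incubation design: 9 + 9 samples, 150 OTUs in
    five modules (sizes 40/30/25/20/15) plus a stable abundant background
    core, sequencing depth 100,000 tags per sample.  ``trait_effect`` scales
    the (negative, by default) coupling of module-1 activity and the hub
    factor into the p-coumaric-acid trait; ``treatment_effect`` is the shift
    of module-1 activity in the biochar group.
    """

    n_samples_per_group: int = 9
    n_otus: int = 150
    n_modules: int = 5
    module_sizes: tuple[int, ...] = (40, 30, 25, 20, 15)
    library_size: int = 100_000
    loading_sd: float = 0.2
    noise_sd: float = 0.5
    trait_effect: float = -1.0
    treatment_effect: float = 2.0
    seed: int = 0
    # trait composition: trait = baseline + trait_effect*(w_act*a1 + w_hub*h) + sd*eps
    trait_baseline: float = 12.0
    trait_noise_sd: float = 0.4
    activity_trait_weight: float = 0.70
    hub_trait_weight: float = 1.10
    # planted hub OTUs (members of module 1)
    hub_genera: tuple[str, ...] = ("Devosia", "Nocardioides")
    hub_otus_per_genus: int = 2
    hub_module_weight: float = 0.96   # cosine of hub profile with module-1 activity
    hub_noise_sd: float = 0.1
    hub_log_abundance: float = 1.5
    # background core
    background_noise_sd: float = 1.0
    background_log_abundance: float = 3.0
    background_log_abundance_sd: float = 0.3
    intercept_sd: float = 0.6
    loading_clip: tuple[float, float] = (0.6, 1.4)

    def __post_init__(self) -> None:
        if len(self.module_sizes) != self.n_modules:
            raise ConfigError("module_sizes length must equal n_modules")
        if sum(self.module_sizes) > self.n_otus:
            raise ConfigError(
                f"module_sizes sum to {sum(self.module_sizes)} > n_otus={self.n_otus}"
            )
        if min((self.n_samples_per_group, self.n_otus, self.library_size), default=1) <= 0:
            raise ConfigError("sizes must be positive")
        n = 2 * self.n_samples_per_group
        if n < self.n_modules + 4:
            raise ConfigError("need at least n_modules + 4 samples for the factor basis")
        n_hub = len(self.hub_genera) * self.hub_otus_per_genus
        if self.hub_genera and n_hub > self.module_sizes[0]:
            raise ConfigError("more hub OTUs than module-1 members")


@dataclass
class SyntheticCommunity:
    """A generated community with its planted ground truth."""

    table: OTUTable
    trait: pd.Series                 # p-coumaric acid, mg/kg, per sample
    module_labels: pd.Series         # planted module of each OTU (0 = background)
    log_abundance: pd.DataFrame      # latent log-abundance profiles (no intercepts)
    activities: pd.DataFrame         # module activity score per sample
    hub_otus: list[str]
    config: CommunityConfig


def gen_community(config: CommunityConfig) -> SyntheticCommunity:
    """Generate an OTU table and coupled trait from a seeded latent model.

    Per sample: module activities form an orthonormal in-sample basis (module
    1 shifted by ``treatment_effect`` in AB along the group contrast); each
    OTU's latent log-abundance is loading x activity of its module plus
    orthogonalised Gaussian noise; counts are multinomial(library_size,
    softmax(log-abundance + intercept)).  The trait couples module-1 activity
    and the hub factor through ``trait_effect``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_per = cfg.n_samples_per_group
    n = 2 * n_per
    samples = [f"NB{i+1}" for i in range(n_per)] + [f"AB{i+1}" for i in range(n_per)]
    treatments = pd.Series(["NB"] * n_per + ["AB"] * n_per, index=samples)
    grp = np.array([0.0] * n_per + [1.0] * n_per)
    contrast = grp - grp.mean()
    gc = contrast / np.linalg.norm(contrast)

    # orthonormal in-sample factors: n_modules activities + hub factor + trait residual
    n_fac = cfg.n_modules + 2
    q, _ = np.linalg.qr(
        np.column_stack([np.ones(n) / np.sqrt(n), gc, rng.normal(size=(n, n_fac))])
    )
    fac = (q[:, 2 : 2 + n_fac] * np.sqrt(n - 1)).T      # unit sample sd, zero mean
    fac = fac * np.sign(rng.normal(size=(n_fac, 1)))    # random orientation
    activities = fac[: cfg.n_modules].copy()
    hub_factor = fac[cfg.n_modules]
    trait_resid = fac[cfg.n_modules + 1]
    activities[0] = activities[0] + cfg.treatment_effect * contrast
    act1_std = activities[0] / activities[0].std()

    # projectors for noise: module OTUs orthogonal to every factor; background
    # orthogonal only to the trait-coupled directions
    def _proj(cols: np.ndarray) -> np.ndarray:
        qb, _ = np.linalg.qr(cols)
        return np.eye(n) - qb @ qb.T

    p_mod = _proj(np.column_stack([np.ones(n), gc, fac.T]))
    p_bg = _proj(
        np.column_stack([np.ones(n), gc, activities[0], hub_factor, trait_resid])
    )

    def _noise(proj: np.ndarray, scale: float) -> np.ndarray:
        e = proj @ rng.normal(size=n)
        sd = e.std()
        if sd == 0:
            return np.zeros(n)
        return scale * e / sd

    labels = np.zeros(cfg.n_otus, dtype=int)
    pos = 0
    for m, size in enumerate(cfg.module_sizes, start=1):
        labels[pos : pos + size] = m
        pos += size

    lo, hi = cfg.loading_clip
    loadings = np.clip(np.abs(rng.normal(1.0, cfg.loading_sd, cfg.n_otus)), lo, hi)
    intercepts = rng.normal(0.0, cfg.intercept_sd, cfg.n_otus)
    latent = np.zeros((cfg.n_otus, n))
    for i in range(cfg.n_otus):
        m = labels[i]
        if m:
            latent[i] = loadings[i] * activities[m - 1] + _noise(p_mod, cfg.noise_sd)
        else:
            latent[i] = _noise(p_bg, cfg.background_noise_sd)
            intercepts[i] = cfg.background_log_abundance + rng.normal(
                0.0, cfg.background_log_abundance_sd
            )

    hub_idx: list[int] = []
    if cfg.hub_genera and cfg.hub_otus_per_genus > 0:
        n_hub = len(cfg.hub_genera) * cfg.hub_otus_per_genus
        sin_h = np.sqrt(1.0 - cfg.hub_module_weight**2)
        for i in range(n_hub):
            latent[i] = (
                cfg.hub_module_weight * act1_std
                + sin_h * hub_factor
                + _noise(p_mod, cfg.hub_noise_sd)
            )
            intercepts[i] = cfg.hub_log_abundance
            hub_idx.append(i)

    trait_vals = (
        cfg.trait_baseline
        + cfg.trait_effect
        * (cfg.activity_trait_weight * act1_std + cfg.hub_trait_weight * hub_factor)
        + cfg.trait_noise_sd * trait_resid
    )

    probs = np.exp(latent + intercepts[:, None])
    probs /= probs.sum(axis=0)
    counts = np.column_stack(
        [rng.multinomial(cfg.library_size, probs[:, s]) for s in range(n)]
    )

    otu_ids = [f"OTU{i+1:04d}" for i in range(cfg.n_otus)]
    pool = _load_genus_pool()
    pool_free = pool[~pool["genus"].isin(cfg.hub_genera)].reset_index(drop=True)
    tax = {}
    for k, otu in enumerate(otu_ids):
        if k in hub_idx:
            genus = cfg.hub_genera[k // cfg.hub_otus_per_genus]
            row = pool[pool["genus"] == genus]
            if row.empty:
                raise ConfigError(f"hub genus {genus!r} not in bundled genus pool")
            tax[otu] = _lineage(row.iloc[0])
        else:
            tax[otu] = _lineage(pool_free.iloc[rng.integers(len(pool_free))])

    table = OTUTable(
        pd.DataFrame(counts, index=otu_ids, columns=samples),
        pd.Series(tax, name="lineage"),
        treatments,
    )
    return SyntheticCommunity(
        table=table,
        trait=pd.Series(trait_vals, index=samples, name="p_CA"),
        module_labels=pd.Series(labels, index=otu_ids, name="module"),
        log_abundance=pd.DataFrame(latent, index=otu_ids, columns=samples),
        activities=pd.DataFrame(
            activities,
            index=[f"module_{m+1}" for m in range(cfg.n_modules)],
            columns=samples,
        ),
        hub_otus=[otu_ids[i] for i in hub_idx],
        config=cfg,
    )


# ---------------------------------------------------------------------------
# environment table

#: per-variable (baseline mean, AB multiplier); multipliers for pH, SOM, AN and
#: p-CA follow the reported treatment responses (+4.52%, +55.05%, -12.77%,
#: -54.84%); the remaining variables are unchanged by treatment.
ENV_DEFAULTS: dict[str, tuple[float, float]] = {
    "pH": (6.5, 1.0452),       # unitless
    "SOM": (20.0, 1.5505),     # g/kg
    "TN": (1.2, 1.0),          # g/kg
    "TP": (0.8, 1.0),          # g/kg
    "TK": (15.0, 1.0),         # g/kg
    "AP": (30.0, 1.0),         # mg/kg
    "AK": (120.0, 1.0),        # mg/kg
    "AN": (90.0, 0.8723),      # mg/kg
    "p_CA": (12.0, 0.4516),    # mg/kg
}


@dataclass
class EnvConfig:
    baselines: dict[str, float] = field(
        default_factory=lambda: {k: v[0] for k, v in ENV_DEFAULTS.items()}
    )
    multipliers: dict[str, float] = field(
        default_factory=lambda: {k: v[1] for k, v in ENV_DEFAULTS.items()}
    )
    cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for k, v in self.baselines.items():
            if v <= 0:
                raise ConfigError(f"baseline mean for {k} must be positive, got {v}")
        if self.cv < 0:
            raise ConfigError("cv must be non-negative")


def gen_env(config: EnvConfig, labels: pd.Series) -> pd.DataFrame:
    """Generate a sample x variable environment table.

    Values are Normal(mean x multiplier_if_AB, cv x group mean), truncated at
    zero; multipliers apply to AB samples only.
    """
    rng = np.random.default_rng(config.seed)
    samples = list(labels.index)
    out = {}
    for var, mean in config.baselines.items():
        mult = config.multipliers.get(var, 1.0)
        vals = np.empty(len(samples))
        for j, s in enumerate(samples):
            mu = mean * (mult if labels[s] == "AB" else 1.0)
            sd = config.cv * mu
            if sd == 0:
                vals[j] = mu
            else:
                v = rng.normal(mu, sd)
                while v <= 0:        # truncate at zero, resample
                    v = rng.normal(mu, sd)
                vals[j] = v
        out[var] = vals
    return pd.DataFrame(out, index=samples)


# ---------------------------------------------------------------------------
# adsorption series

#: batch geometry of the sorption experiments: 5 g biochar in 50 mL solution,
#: kinetics at C0 = 150 mg/L sampled every 15 min to 135 min, isotherms at
#: six initial concentrations from 20 to 360 mg/L.
KINETIC_TIMES_MIN = (15.0, 30.0, 45.0, 60.0, 75.0, 90.0, 105.0, 120.0, 135.0)
ISOTHERM_C0_MG_L = (20.0, 40.0, 60.0, 120.0, 240.0, 360.0)

# kinetic defaults sit inside the mass-balance envelope C0*V/M = 1.5 mg/g
_DEFAULT_PARAMS = {
    "pke": {"Qe": 1.2, "k": 0.1},
    "elovich": {"a": 0.2, "b": 0.2},
    "idm": {"kp": 0.1, "c": 0.1},
    "langmuir": {"Qmax": 5.205, "KL": 0.08},
    "freundlich": {"KF": 1.0, "n": 2.0},
}


@dataclass
class AdsorptionSimConfig:
    model: str = "pke"
    params: dict[str, float] = field(default_factory=dict)
    times: tuple[float, ...] = KINETIC_TIMES_MIN
    c0_list: tuple[float, ...] = ISOTHERM_C0_MG_L
    c0: float = 150.0
    volume_l: float = 0.050
    mass_g: float = 5.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        model = self.model.lower()
        valid = KINETIC_MODELS + ISOTHERM_MODELS
        if model not in valid:
            raise ConfigError(f"unknown model {self.model!r}; valid models: {valid}")
        self.model = model
        merged = dict(_DEFAULT_PARAMS[model])
        merged.update(self.params)
        self.params = merged
        if model in KINETIC_MODELS and np.any(np.diff(self.times) <= 0):
            raise ConfigError("sampling times must be strictly increasing")


def _equilibrium_ce(model: str, params: dict, c0: float, vm_ratio: float) -> float:
    """Solve mass balance Qe=(C0-Ce)/vm against the isotherm for Ce."""
    from scipy.optimize import brentq

    if model == "langmuir":
        iso = lambda ce: langmuir_curve(ce, params["Qmax"], params["KL"])
    else:
        iso = lambda ce: freundlich_curve(ce, params["KF"], params["n"])
    f = lambda ce: (c0 - ce) / vm_ratio - iso(ce)
    return brentq(f, 1e-12, c0)


def gen_adsorption(config: AdsorptionSimConfig) -> AdsorptionSeries:
    """Simulate a kinetic or isotherm series from a closed-form model.

    Gaussian noise (sd ``noise_sd``, mg/g) is added to the adsorbed quantity,
    clipped so concentrations stay within [0, C0]; the solution concentration
    is back-computed through the mass balance so the series round-trips.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    vm = cfg.mass_g / cfg.volume_l        # g/L
    if cfg.model in KINETIC_MODELS:
        t = np.asarray(cfg.times, dtype=float)
        p = cfg.params
        if cfg.model == "pke":
            q = pke_curve(t, p["Qe"], p["k"])
        elif cfg.model == "elovich":
            q = elovich_curve(t, p["a"], p["b"])
        else:
            q = idm_curve(t, p["kp"], p["c"])
        q = q + rng.normal(0.0, cfg.noise_sd, t.size)
        q = np.clip(q, 0.0, cfg.c0 / vm)
        ct = cfg.c0 - q * vm
        return AdsorptionSeries(
            mode="kinetic", c0=cfg.c0, conc=ct, t=t,
            volume_l=cfg.volume_l, mass_g=cfg.mass_g,
        )
    c0s = np.asarray(cfg.c0_list, dtype=float)
    ce = np.array([_equilibrium_ce(cfg.model, cfg.params, c, vm) for c in c0s])
    qe = (c0s - ce) / vm
    q_meas = None
    if cfg.noise_sd > 0:
        # measurement noise lives on the measured adsorbed quantity; Ce keeps
        # the equilibrium value (a mass-balance back-computation would amplify
        # the error by M/V, here 100 g/L)
        q_meas = np.clip(qe + rng.normal(0.0, cfg.noise_sd, c0s.size), 1e-9, None)
    return AdsorptionSeries(
        mode="isotherm", c0=c0s, conc=ce,
        volume_l=cfg.volume_l, mass_g=cfg.mass_g, q_measured=q_meas,
    )


# ---------------------------------------------------------------------------
# structural-equation data with exactly planted standardized paths

SEM_DEFAULT_PATHS: dict[tuple[str, str], float] = {
    ("biochar", "SOM"): 0.866,
    ("biochar", "p_CA"): -0.623,
    ("SOM", "Shannon"): 0.504,
    ("SOM", "hub_abundance"): 0.472,
    ("Shannon", "acd_abundance"): 0.30,
    ("hub_abundance", "acd_abundance"): 0.485,
    ("acd_abundance", "p_CA"): -0.30,
}


def gen_sem_data(
    n: int = 200,
    seed: int = 0,
    paths: dict[tuple[str, str], float] | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str], float]]:
    """Simulate indicator data whose standardized paths equal given truths.

    Variables are built in causal order; each structural residual is
    orthogonalised against every previously generated column and scaled so
    that all sample (co)variances equal the implied values exactly.  The
    standardized OLS path coefficients of the generated sample therefore
    match the planted truths to machine precision, for any seed.  The first
    variable is a balanced binary treatment (n must be even).
    """
    if n % 2:
        raise ConfigError("n must be even (balanced binary treatment)")
    paths = dict(SEM_DEFAULT_PATHS if paths is None else paths)
    variables: list[str] = []
    for src, dst in paths:
        for v in (src, dst):
            if v not in variables:
                variables.append(v)
    parents_of = {v: [s for (s, d) in paths if d == v] for v in variables}
    order: list[str] = []
    while len(order) < len(variables):
        ready = [
            v for v in variables
            if v not in order and all(p in order for p in parents_of[v])
        ]
        if not ready:
            raise ConfigError("planted path structure is cyclic")
        order.extend(ready)
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    root = order[0]
    treat = np.r_[np.zeros(n // 2), np.ones(n // 2)]
    cols[root] = (treat - treat.mean()) / treat.std(ddof=1)

    def _resid() -> np.ndarray:
        prev = np.column_stack([np.ones(n)] + [cols[v] for v in cols])
        q, _ = np.linalg.qr(prev)
        e = rng.normal(size=n)
        e = e - q @ (q.T @ e)
        return e / e.std(ddof=1)

    for var in order[1:]:
        parents = [s for (s, d) in paths if d == var]
        beta = np.array([paths[(s, var)] for s in parents])
        xm = np.column_stack([cols[s] for s in parents])
        cov = (xm.T @ xm) / (n - 1)       # exact sample covariance of parents
        explained = float(beta @ cov @ beta)
        if explained >= 1.0:
            raise ConfigError(
                f"planted paths into {var!r} imply variance {explained:.3f} >= 1"
            )
        cols[var] = xm @ beta + np.sqrt(1.0 - explained) * _resid()
    data = pd.DataFrame(cols)
    data[root] = treat          # raw 0/1 coding; model standardises internally
    return data, paths


# ---------------------------------------------------------------------------
# writers

def write_otu_table(table: OTUTable, counts_path, taxonomy_path, labels_path) -> None:
    """Write counts TSV, taxonomy TSV and labels CSV in the loadable formats."""
    table.counts.to_csv(counts_path, sep="\t", index_label="OTU_ID")
    table.taxonomy.to_csv(taxonomy_path, sep="\t", header=False)
    table.treatments.rename("treatment").to_csv(labels_path, index_label="sample")


def write_env(env: pd.DataFrame, path) -> None:
    env.to_csv(path, index_label="sample")


def write_adsorption(series: AdsorptionSeries, path) -> None:
    if series.mode == "kinetic":
        df = pd.DataFrame(
            {"t_min": series.t, "Ct_mg_L": series.conc, "Qt_mg_g": series.q}
        )
    else:
        df = pd.DataFrame(
            {"C0_mg_L": series.c0, "Ce_mg_L": series.conc, "Qe_mg_g": series.q}
        )
    df.to_csv(path, index=False)
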