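"""Synthetic multi-dataset expression compendia with planted co-expression modules.

The generator emulates the structure the discovery pipeline is designed to
exploit: several datasets sharing a gene universe, groups of co-regulated
genes whose expression is driven by a per-sample binary latent state (the
"on/off" pattern that makes them bimodal), a per-array additive quality
offset shared by all genes of a sample, dependence between module latents
via a thresholded Gaussian copula, and microenvironment-extrinsic modules
that are coherent in tumor datasets but decohere in cell-line datasets.

A companion generator produces clinical annotation (survival, chemotherapy
response, subtype and receptor labels, metastatic site) driven by the planted
latent states, so downstream association statistics can be validated against
known effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._seeds import derive_seed
from .preprocess import Compendium, ExpressionDataset

_MIN_LOADING = 0.2  # floor of the multiplicative per-gene loading jitter


@dataclass
class PlantedModule:
    """A planted co-regulated gene group.

    ``activation_prob`` is the fraction of samples with the module "on";
    ``effect`` is the on/off mean shift in log2 units; ``loading_sd`` scales
    per-gene heterogeneity of that shift; ``extrinsic`` modules lose their
    co-expression (independent per-gene latents) in cell-line datasets.
    """

    name: str
    size: int
    activation_prob: float = 0.3
    effect: float = 3.0
    loading_sd: float = 0.3
    extrinsic: bool = False

    def __post_init__(self) -> None:
        if self.size < 3:
            raise ValueError(f"module {self.name}: size must be >= 3")
        if self.effect <= 0:
            raise ValueError(f"module {self.name}: effect must be positive")
        if not (0.0 < self.activation_prob < 1.0):
            raise ValueError(f"module {self.name}: activation_prob must be in (0,1)")


@dataclass
class SimulationConfig:
    n_datasets: int = 6
    contexts: list[str] | None = None  # per-dataset "tumor"/"cell_line"; default all tumor
    n_genes: int = 3000
    n_samples: int = 120
    modules: list[PlantedModule] = field(default_factory=list)
    quality_sd: float = 0.5
    noise_sd: float = 1.0
    latent_coupling: np.ndarray | None = None  # symmetric PSD, unit diagonal
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.contexts is None:
            self.contexts = ["tumor"] * self.n_datasets
        if len(self.contexts) != self.n_datasets:
            raise ValueError("contexts must have one entry per dataset")
        if self.quality_sd < 0 or self.noise_sd <= 0:
            raise ValueError("quality_sd must be >= 0 and noise_sd > 0")
        total = sum(m.size for m in self.modules)
        if total > self.n_genes:
            raise ValueError(
                f"planted module genes ({total}) exceed n_genes ({self.n_genes})"
            )
        k = len(self.modules)
        if self.latent_coupling is None:
            self.latent_coupling = np.eye(k)
        else:
            self.latent_coupling = np.asarray(self.latent_coupling, dtype=float)
            C = self.latent_coupling
            if C.shape != (k, k):
                raise ValueError("latent_coupling shape must match number of modules")
            if not np.allclose(C, C.T, atol=1e-12) or not np.allclose(np.diag(C), 1.0):
                raise ValueError("latent_coupling must be symmetric with unit diagonal")
            if np.linalg.eigvalsh(C).min() < -1e-10:
                raise ValueError("latent_coupling must be positive semi-definite")


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The study's standard synthetic setting: 6 tumor datasets of 120 samples,
    3,000 genes, 5 planted modules of 40 genes each (effect 3, noise sd 1)."""
    modules = [PlantedModule(name=f"M{i + 1}", size=40) for i in range(5)]
    cfg = dict(
        n_datasets=6,
        n_genes=3000,
        n_samples=120,
        modules=modules,
        seed=seed,
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)


@dataclass
class SimulationTruth:
    """Planted memberships, latent states, loadings, and optional clinical table."""

    gene_membership: dict[str, str | None]
    latent_activity: dict[str, dict[str, np.ndarray]]  # dataset -> module -> 0/1 states
    loadings: dict[str, np.ndarray]  # module -> per-gene multiplicative loading
    module_names: list[str]
    clinical: pd.DataFrame | None = None

    def module_genes(self, name: str) -> list[str]:
        return [g for g, m in self.gene_membership.items() if m == name]


def _correlated_states(
    rng: np.random.Generator, probs: np.ndarray, coupling: np.ndarray, n: int
) -> np.ndarray:
    """Binary latent states (modules x samples) from a thresholded Gaussian copula."""
    k = len(probs)
    if k == 0:
        return np.zeros((0, n), dtype=int)
    L = np.linalg.cholesky(coupling + 1e-10 * np.eye(k))
    z = L @ rng.standard_normal((k, n))
    thresh = norm.ppf(probs)[:, None]
    return (z < thresh).astype(int)


def generate_compendium(config: SimulationConfig) -> tuple[Compendium, SimulationTruth]:
    """Generate the synthetic compendium and its ground truth.

    Each dataset's matrix is baseline + effect * latent * loading for planted
    genes, plus a per-array quality offset shared by all genes of a sample,
    plus iid Gaussian noise.  Same config and seed give bit-identical output.
    """
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    membership: dict[str, str | None] = {g: None for g in genes}
    pos = 0
    module_slices: dict[str, slice] = {}
    for m in config.modules:
        module_slices[m.name] = slice(pos, pos + m.size)
        for g in genes[pos : pos + m.size]:
            membership[g] = m.name
        pos += m.size

    rng_global = np.random.default_rng(derive_seed(config.seed, "compendium"))
    baseline = rng_global.normal(config.baseline_mean, config.baseline_sd, config.n_genes)
    loadings = {
        m.name: np.maximum(
            _MIN_LOADING, 1.0 + rng_global.normal(0.0, m.loading_sd, m.size)
        )
        for m in config.modules
    }

    probs = np.array([m.activation_prob for m in config.modules])
    datasets = []
    latent_activity: dict[str, dict[str, np.ndarray]] = {}
    for d in range(config.n_datasets):
        ds_id = f"D{d + 1}"
        context = config.contexts[d]
        rng = np.random.default_rng(derive_seed(config.seed, "dataset", ds_id))
        n = config.n_samples
        states = _correlated_states(rng, probs, config.latent_coupling, n)

        X = np.tile(baseline[:, None], (1, n))
        latent_activity[ds_id] = {}
        for mi, m in enumerate(config.modules):
            sl = module_slices[m.name]
            if m.extrinsic and context == "cell_line":
                # decohered: each gene flips its own independent latent
                gene_states = rng.binomial(1, m.activation_prob, size=(m.size, n))
                X[sl] += m.effect * loadings[m.name][:, None] * gene_states
            else:
                X[sl] += m.effect * np.outer(loadings[m.name], states[mi])
                latent_activity[ds_id][m.name] = states[mi].copy()
        X += rng.normal(0.0, config.quality_sd, n)[None, :]  # per-array quality offset
        X += rng.normal(0.0, config.noise_sd, X.shape)

        datasets.append(
            ExpressionDataset(
                dataset_id=ds_id,
                context=context,
                gene_ids=list(genes),
                sample_ids=[f"{ds_id}_s{j:04d}" for j in range(n)],
                values=X,
            )
        )

    comp = Compendium(datasets, list(genes))
    truth = SimulationTruth(
        gene_membership=membership,
        latent_activity=latent_activity,
        loadings=loadings,
        module_names=[m.name for m in config.modules],
    )
    return comp, truth


_SUBTYPE_RULE = {(1, 1): "LumB", (1, 0): "LumA", (0, 1): "Basal", (0, 0): "Normal"}


def generate_clinical(
    truth: SimulationTruth,
    hazard_coeffs: dict[str, float],
    logistic_coeffs: dict[str, float],
    censoring_rate: float = 0.2,
    baseline_hazard: float = 0.1,
    logistic_intercept: float = -0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Clinical annotation driven by the planted latent states.

    Survival times are exponential with log-hazard linear in the latent
    states; censoring is an independent exponential with rate
    ``censoring_rate`` (0 means no censoring).  Pathologic complete response
    (pCR) follows a logistic model on the latents.  Subtype is a fixed
    deterministic function of the first two modules' states (on/on LumB,
    on/off LumA, off/on Basal, off/off Normal); ER status mirrors module 1
    and HER2 status module 2.  Metastatic site (bone vs. lung/brain) uses the
    pCR linear predictor through a logistic draw.
    """
    for name in list(hazard_coeffs) + list(logistic_coeffs):
        if name not in truth.module_names:
            raise ValueError(f"unknown module name {name!r}")
    rng = np.random.default_rng(derive_seed(seed, "clinical"))
    rows = []
    for ds_id, mods in truth.latent_activity.items():
        if not mods:
            continue
        names = list(mods)
        states = np.vstack([mods[m] for m in names])
        n = states.shape[1]
        loghaz = np.zeros(n)
        for i, m in enumerate(names):
            loghaz += hazard_coeffs.get(m, 0.0) * states[i]
        t_event = rng.exponential(1.0 / (baseline_hazard * np.exp(loghaz)))
        if censoring_rate > 0:
            t_cens = rng.exponential(1.0 / censoring_rate, size=n)
        else:
            t_cens = np.full(n, np.inf)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)

        lp = np.full(n, float(logistic_intercept))
        for i, m in enumerate(names):
            lp += logistic_coeffs.get(m, 0.0) * states[i]
        pcr = rng.binomial(1, 1.0 / (1.0 + np.exp(-lp)))
        met_bone = rng.binomial(1, 1.0 / (1.0 + np.exp(-lp)))

        s1 = states[0] if len(names) >= 1 else np.zeros(n, dtype=int)
        s2 = states[1] if len(names) >= 2 else np.zeros(n, dtype=int)
        subtype = [_SUBTYPE_RULE[(int(a), int(b))] for a, b in zip(s1, s2)]
        sample_ids = [f"{ds_id}_s{j:04d}" for j in range(n)]
        met_site = np.where(met_bone == 1, "bone", rng.choice(["lung", "brain"], size=n))
        rows.append(
            pd.DataFrame(
                {
                    "sample_id": sample_ids,
                    "dataset_id": ds_id,
                    "time": time,
                    "event": event,
                    "pcr": pcr,
                    "subtype": subtype,
                    "er_status": s1,
                    "her2_status": s2,
                    "met_site": met_site,
                }
            )
        )
    clinical = pd.concat(rows, ignore_index=True)
    truth.clinical = clinical
    return clinical
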