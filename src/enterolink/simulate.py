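"""Synthetic multi-omics cohort generator.

Emulates the study design the pipeline targets: a small dairy-cow cohort
stratified into two rumen enterotypes (4 vs 8 animals), one driven by
*Prevotella*-like dominance and the other by a *Ruminococcus*-like balance,
with three metabolome layers (rumen, serum, milk) organised into correlated
feature blocks, and a linear causal chain

    microbiome contrast -> rumen module -> serum module -> milk module -> MPY

planted through one designated block per layer. Every generator is
deterministic under its seed; ground truth (labels, drivers, block maps,
latents, path coefficients) is returned alongside the tables so downstream
recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .datatypes import AbundanceTable, OmicsMatrix, PhenotypeTable

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "simulate_genus_table",
    "simulate_metabolome",
    "simulate_chain_phenotype",
    "simulate_vfa_table",
    "simulate_cohort",
    "VFA_GROUP_MEANS",
    "VFA_SEM",
]

DEFAULT_SEED = 20230509

#: expected relative abundance of the two driver genera per enterotype,
#: as fractions (driver1 = Prevotella-like, driver2 = Ruminococcus-like)
DRIVER_TARGETS = {
    "type1": (0.3676, 0.0474),
    "type2": (0.2246, 0.2467),
}

#: per-group VFA concentration means (mmol/L scale) and pooled SEMs
VFA_GROUP_MEANS = pd.DataFrame(
    {
        "type1": [81.96, 34.46, 0.93, 15.22, 1.60, 2.30],
        "type2": [84.56, 33.14, 1.04, 15.49, 1.84, 2.28],
    },
    index=["acetate", "propionate", "isobutyrate", "butyrate", "isovalerate", "valerate"],
)
VFA_SEM = pd.Series(
    [3.537, 1.962, 0.0629, 0.864, 0.114, 0.117],
    index=VFA_GROUP_MEANS.index,
)

METAB_LAYERS = ("rumen_metab", "serum_metab", "milk_metab")


@dataclass
class SimConfig:
    """Cohort generator configuration.

    Defaults reproduce the reference study design: 4 + 8 animals, 60 genera,
    metabolome layers of 260/113/94 features organised into 10/5/7 blocks,
    and MPY centred at 1.16 kg/d. ``chain_coefs`` are standardized path
    coefficients; with ``chain_noise_sd=None`` disturbance SDs are set to
    sqrt(1 - coef^2) so every chain latent has unit variance and the implied
    microbiome->MPY correlation is the product of the coefficients.
    """

    n_type1: int = 4
    n_type2: int = 8
    n_genera: int = 60
    driver_shift: float = 1.0
    genus_sigma: float = 0.35
    n_satellites: int = 8
    satellite_shift: float = 1.0
    satellite_cor: float = 0.7
    n_features: dict = field(
        default_factory=lambda: {"rumen_metab": 260, "serum_metab": 113, "milk_metab": 94}
    )
    n_blocks: dict = field(
        default_factory=lambda: {"rumen_metab": 10, "serum_metab": 5, "milk_metab": 7}
    )
    within_block_cor: float = 0.8
    chain_coefs: tuple = (0.9, 0.9, 0.9, 0.9)  # alpha, beta_c, gamma, delta
    chain_noise_sd: tuple | None = None
    mpy_mean: float = 1.16
    mpy_sd: float = 0.17
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_type1 < 2 or self.n_type2 < 2:
            raise ValueError("each enterotype needs >= 2 samples")
        if not 0 <= self.within_block_cor < 1:
            raise ValueError("within_block_cor must lie in [0, 1)")
        if not all(np.isfinite(self.chain_coefs)):
            raise ValueError("chain coefficients must be finite")
        if self.n_genera < 3:
            raise ValueError("need at least 3 genera")

    @property
    def n_samples(self) -> int:
        return self.n_type1 + self.n_type2

    @property
    def sample_ids(self) -> list[str]:
        return [f"cow{i + 1:02d}" for i in range(self.n_samples)]

    @property
    def labels(self) -> np.ndarray:
        return np.array([1] * self.n_type1 + [2] * self.n_type2)

    def noise_sds(self) -> np.ndarray:
        if self.chain_noise_sd is not None:
            return np.asarray(self.chain_noise_sd, dtype=float)
        c = np.asarray(self.chain_coefs, dtype=float)
        return np.sqrt(np.clip(1.0 - c**2, 0.0, None))


@dataclass
class SyntheticTruth:
    """Ground truth emitted with a simulated cohort."""

    labels: pd.Series | None = None
    driver_ids: tuple = ("Prevotella_like", "Ruminococcus_like")
    block_map: dict = field(default_factory=dict)  # layer -> feature_id -> block index
    coupled_block: dict = field(default_factory=dict)  # layer -> block index on the chain
    latents: dict = field(default_factory=dict)  # name -> per-sample latent (pd.Series)
    satellites: dict = field(default_factory=dict)  # driver id -> satellite genus ids
    chain_coefs: tuple = ()

    def to_dict(self) -> dict:
        return {
            "labels": None if self.labels is None else self.labels.to_dict(),
            "driver_ids": list(self.driver_ids),
            "block_map": self.block_map,
            "coupled_block": self.coupled_block,
            "latents": {k: v.to_dict() for k, v in self.latents.items()},
            "satellites": self.satellites,
            "chain_coefs": list(self.chain_coefs),
        }


def _child_seed(seed: int, offset: int) -> int:
    return (int(seed) + 7919 * offset) % (2**31 - 1)


def simulate_genus_table(cfg: SimConfig, seed: int | None = None):
    """Simulate the samples x genera relative-abundance table.

    Genus intensities are log-normal around genus-specific mean masses and
    closed to proportions. The two driver genera get group-specific mean
    masses interpolated on the log scale between a common midpoint
    (``driver_shift = 0``: no planted effect) and targets whose expected
    closed proportions match the reference enterotype profiles
    (``driver_shift = 1``). Each driver additionally carries
    ``n_satellites`` satellite genera whose log-masses shift with the same
    group pattern (scaled by ``driver_shift``), emulating the co-varying
    sub-communities that make enterotypes detectable as microbial modules.
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(_child_seed(seed, 1))
    n, g = cfg.n_samples, cfg.n_genera
    labels = cfg.labels

    # non-driver mean masses: geometric decay, fixed total mass 1
    n_bg = g - 2
    bg = 0.85 ** np.arange(n_bg)
    bg /= bg.sum()

    # driver mean masses per group, chosen so expected closed proportions hit
    # the targets: mass_j = target_j / (1 - sum(targets)) given bg total 1
    log_mass = {}
    for group, (a, b) in DRIVER_TARGETS.items():
        s = a + b
        log_mass[group] = np.log(np.array([a, b]) / (1.0 - s))
    mid = (log_mass["type1"] + log_mass["type2"]) / 2.0
    shifted = {
        grp: mid + cfg.driver_shift * (log_mass[grp] - mid) for grp in ("type1", "type2")
    }

    # satellite genera: mid-rank background genera whose log-mass follows the
    # driver's group pattern (+s/2 in the driver's dominant type, -s/2 in the
    # other), scaled by driver_shift
    n_sat = min(cfg.n_satellites, max((n_bg - 4) // 2, 0))
    sat1 = np.arange(10, 10 + n_sat) % n_bg
    sat2 = np.arange(10 + n_sat, 10 + 2 * n_sat) % n_bg
    s = cfg.satellite_shift * cfg.driver_shift / 2.0

    sigma = cfg.genus_sigma
    means = np.empty((n, g))
    for i in range(n):
        grp = "type1" if labels[i] == 1 else "type2"
        means[i, :2] = np.exp(shifted[grp])
        row_bg = bg.copy()
        sign = 1.0 if grp == "type1" else -1.0
        row_bg[sat1] *= np.exp(sign * s)
        row_bg[sat2] *= np.exp(-sign * s)
        row_bg /= row_bg.sum()  # mass-preserving: driver targets stay on target
        means[i, 2:] = row_bg
    # lognormal with E[x] = mean  =>  mu = log(mean) - sigma^2/2; satellite
    # log-noise shares the driver's sample-level noise with correlation
    # satellite_cor, so driver sub-communities co-vary within groups too
    z = rng.standard_normal((n, g))
    r_sat = cfg.satellite_cor * cfg.driver_shift
    mix = np.sqrt(max(1.0 - r_sat**2, 0.0))
    for cols, drv in ((sat1 + 2, 0), (sat2 + 2, 1)):
        z[:, cols] = r_sat * z[:, [drv]] + mix * z[:, cols]
    x = np.exp(np.log(means) - sigma**2 / 2.0 + sigma * z)
    x /= x.sum(axis=1, keepdims=True)

    taxa = list(SyntheticTruth().driver_ids) + [f"genus{j:03d}" for j in range(n_bg)]
    table = AbundanceTable(pd.DataFrame(x, index=cfg.sample_ids, columns=taxa))

    truth = SyntheticTruth(labels=pd.Series(labels, index=cfg.sample_ids), chain_coefs=tuple(cfg.chain_coefs))
    truth.satellites = {
        taxa[0]: [taxa[2 + j] for j in sat1],
        taxa[1]: [taxa[2 + j] for j in sat2],
    }
    # microbiome latent: standardized log driver contrast (driver2 vs driver1)
    contrast = np.log(x[:, 1] + 1e-12) - np.log(x[:, 0] + 1e-12)
    z = (contrast - contrast.mean()) / contrast.std(ddof=0)
    truth.latents["micro"] = pd.Series(z, index=cfg.sample_ids)
    return table, truth


def simulate_chain_phenotype(cfg: SimConfig, truth: SyntheticTruth, seed: int | None = None) -> PhenotypeTable:
    """Propagate the causal chain from the microbiome latent down to MPY.

    M_rumen = a*E_micro + e1, M_serum = b*M_rumen + e2, M_milk = c*M_serum + e3,
    MPY_z = d*M_milk + e4; MPY = mpy_mean + mpy_sd * MPY_z. Latents are stored
    in ``truth.latents`` for the metabolome generators to couple to.
    """
    if "micro" not in truth.latents:
        raise ValueError("truth lacks the microbiome latent; run simulate_genus_table first")
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(_child_seed(seed, 2))
    a, b, c, d = cfg.chain_coefs
    sds = cfg.noise_sds()
    idx = truth.latents["micro"].index
    n = len(idx)

    e = truth.latents["micro"].to_numpy()
    m_rumen = a * e + rng.normal(0, sds[0], n)
    m_serum = b * m_rumen + rng.normal(0, sds[1], n)
    m_milk = c * m_serum + rng.normal(0, sds[2], n)
    mpy_z = d * m_milk + rng.normal(0, sds[3], n)

    truth.latents["rumen_metab"] = pd.Series(m_rumen, index=idx)
    truth.latents["serum_metab"] = pd.Series(m_serum, index=idx)
    truth.latents["milk_metab"] = pd.Series(m_milk, index=idx)
    truth.latents["mpy_z"] = pd.Series(mpy_z, index=idx)

    mpy = np.maximum(cfg.mpy_mean + cfg.mpy_sd * mpy_z, 0.0)
    pheno = pd.DataFrame({"MPY": mpy}, index=idx)
    labels = truth.labels if truth.labels is not None else None
    return PhenotypeTable(pheno, group_label=labels)


def simulate_metabolome(cfg: SimConfig, layer: str, truth: SyntheticTruth | None = None, seed: int | None = None):
    """Simulate one metabolome layer as block-correlated features.

    Each block has a per-sample latent factor; features load on their block
    factor with loading sqrt(rho) so the within-block feature correlation is
    ``within_block_cor`` and between-block correlation is ~0. If ``truth``
    carries a chain latent for the layer, block 0 uses its standardized value
    as the factor, coupling the block to the causal chain.
    """
    if layer not in METAB_LAYERS:
        raise ValueError(f"unknown metabolome layer {layer!r}")
    rho = cfg.within_block_cor
    if rho >= 1:
        raise ValueError("within_block_cor must be < 1")
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(_child_seed(seed, 3 + METAB_LAYERS.index(layer)))

    n = cfg.n_samples
    p = cfg.n_features[layer]
    n_blocks = cfg.n_blocks[layer]
    sizes = np.full(n_blocks, p // n_blocks)
    sizes[: p % n_blocks] += 1

    factors = rng.standard_normal((n, n_blocks))
    if truth is not None and layer in truth.latents:
        lat = truth.latents[layer].to_numpy()
        factors[:, 0] = (lat - lat.mean()) / lat.std(ddof=0)

    lam = np.sqrt(rho)
    cols, vals, block_of = [], [], {}
    j = 0
    for b, size in enumerate(sizes):
        eps = rng.standard_normal((n, size))
        block = lam * factors[:, [b]] + np.sqrt(1 - rho) * eps
        vals.append(block)
        for _ in range(size):
            fid = f"{layer[:1]}m{j:03d}"
            cols.append(fid)
            block_of[fid] = int(b)
            j += 1
    data = pd.DataFrame(np.hstack(vals), index=cfg.sample_ids, columns=cols)

    if truth is None:
        truth = SyntheticTruth()
    truth.block_map[layer] = block_of
    truth.coupled_block[layer] = 0
    return OmicsMatrix(data, layer_tag=layer), truth


def simulate_vfa_table(cfg: SimConfig, seed: int | None = None, sd_scale: float = 1.0) -> PhenotypeTable:
    """Simulate six rumen VFA concentrations around the reference group means.

    Per-sample values are normal around the group mean with the SD implied by
    the printed pooled SEM at the reference design of 4 + 8 animals
    (sd = SEM * sqrt(16/3), the harmonic-mean group size); negative draws are
    truncated at zero with a warning.
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(_child_seed(seed, 9))
    labels = cfg.labels
    n_h_ref = 2.0 / (1.0 / 4 + 1.0 / 8)  # the reference study's group sizes
    sds = VFA_SEM.to_numpy() * np.sqrt(n_h_ref) * sd_scale

    out = np.empty((cfg.n_samples, len(VFA_GROUP_MEANS)))
    for i, lab in enumerate(labels):
        mu = VFA_GROUP_MEANS["type1" if lab == 1 else "type2"].to_numpy()
        out[i] = rng.normal(mu, sds)
    if np.any(out < 0):
        warnings.warn("negative VFA draws truncated at 0", UserWarning, stacklevel=2)
        out = np.clip(out, 0.0, None)
    df = pd.DataFrame(out, index=cfg.sample_ids, columns=list(VFA_GROUP_MEANS.index))
    return PhenotypeTable(df, group_label=pd.Series(labels, index=cfg.sample_ids))


def simulate_cohort(cfg: SimConfig | None = None, seed: int | None = None) -> dict:
    """Generate the full cohort: genus table, chain phenotype, three metabolome
    layers, VFA table, and ground truth. Returns a dict of artifacts."""
    cfg = cfg or SimConfig()
    seed = cfg.seed if seed is None else seed
    genus, truth = simulate_genus_table(cfg, seed)
    phenotype = simulate_chain_phenotype(cfg, truth, seed)
    layers = {}
    for layer in METAB_LAYERS:
        layers[layer], truth = simulate_metabolome(cfg, layer, truth, seed)
    vfa = simulate_vfa_table(cfg, seed)
    return {
        "genus": genus,
        "phenotype": phenotype,
        "layers": layers,
        "vfa": vfa,
        "truth": truth,
        "config": cfg,
    }
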