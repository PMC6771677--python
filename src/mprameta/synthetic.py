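"""Synthetic MPRA data generators.

Every downstream stage of the pipeline consumes data with the statistical
structure produced here: Gamma-distributed plasmid (DNA) counts with RNA
counts Poisson-distributed around ``alpha * plasmid``, paired datasets whose
activity decomposes into shared and cell-type-specific components, sequences
with planted transcription-factor motifs, and saturation-mutagenesis variant
tables with sparse additive per-position effects.

All generators are pure functions of their configuration, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "PairedSimConfig",
    "SatMutSimConfig",
    "simulate_counts",
    "simulate_sequences",
    "simulate_paired_datasets",
    "simulate_saturation",
]

NUCLEOTIDES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a single barcode-count simulation.

    Parameters
    ----------
    n_regions : int
        Number of candidate regions (excluding negative controls).
    n_controls : int
        Number of negative-control regions; controls draw their
        transcription rate from the inactive component.
    barcodes_per_region : int
        Barcodes tagging each region.
    dna_gamma_shape, dna_gamma_scale : float
        Shape and scale of the Gamma distribution of plasmid copies per
        barcode; the scale is the expected copy number per unit shape.
    alpha_log2_mean : float
        log2 shift of the active component's transcription rate relative
        to the inactive component (whose log2 alpha is centred at 0).
    alpha_log2_sd : float
        Spread of log2 alpha within each component.
    active_fraction : float
        Fraction of non-control regions drawn from the active component.
    rna_depth_factor : float
        Multiplicative RNA sequencing-depth factor.
    seed : int
        Seed for all randomness in the simulation.
    """

    n_regions: int = 500
    n_controls: int = 100
    barcodes_per_region: int = 30
    dna_gamma_shape: float = 4.0
    dna_gamma_scale: float = 25.0
    alpha_log2_mean: float = 2.0
    alpha_log2_sd: float = 0.5
    active_fraction: float = 0.3
    rna_depth_factor: float = 1.0
    seed: int = 0
    barcode_effect_sd: float = 0.0

    def validate(self) -> None:
        for name in ("n_regions", "n_controls", "barcodes_per_region"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("dna_gamma_shape", "dna_gamma_scale", "rna_depth_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.alpha_log2_sd < 0:
            raise ValueError(f"alpha_log2_sd must be >= 0, got {self.alpha_log2_sd}")
        if not 0.0 <= self.active_fraction <= 1.0:
            raise ValueError(
                f"active_fraction must be in [0, 1], got {self.active_fraction}"
            )
        if self.barcode_effect_sd < 0:
            raise ValueError(
                f"barcode_effect_sd must be >= 0, got {self.barcode_effect_sd}"
            )


@dataclass(frozen=True)
class PairedSimConfig:
    """Two datasets over the same regions with shared + specific activity."""

    base: SimConfig = field(default_factory=SimConfig)
    shared_feature_count: int = 10
    specific_feature_count: int = 10
    shared_effect_sd: float = 1.0
    specific_effect_sd: float = 1.0
    noise_sd: float = 0.5

    def validate(self) -> None:
        self.base.validate()
        for name in ("shared_effect_sd", "specific_effect_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.shared_feature_count < 0 or self.specific_feature_count < 0:
            raise ValueError("feature counts must be >= 0")


@dataclass(frozen=True)
class SatMutSimConfig:
    """Saturation-mutagenesis simulation: sparse additive per-position effects.

    Nonzero effects arise from disrupting transcription-factor binding sites
    planted in the element, the dominant mechanism in real regulatory
    saturation data: ``effect_sparsity`` is the fraction of positions covered
    by planted sites, ``motif_width`` their length, and the effect of a
    substitution inside a site is the site strength times the change in the
    motif's log-odds score at that offset, rescaled so nonzero effects have
    spread ``effect_sd``. Positions outside any site have exactly zero
    effect (the null mass).
    """

    element_length: int = 300
    train_fraction: float = 0.25
    effect_sparsity: float = 0.2
    effect_sd: float = 1.0
    noise_sd: float = 0.1
    class_threshold: float = 0.5
    motif_width: int = 8
    site_strength_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.element_length < 1:
            raise ValueError(f"element_length must be >= 1, got {self.element_length}")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError(
                f"train_fraction must be in (0, 1), got {self.train_fraction}"
            )
        if not 0.0 <= self.effect_sparsity <= 1.0:
            raise ValueError(
                f"effect_sparsity must be in [0, 1], got {self.effect_sparsity}"
            )
        if self.class_threshold < 0:
            raise ValueError(
                f"class_threshold must be >= 0, got {self.class_threshold}"
            )
        if self.motif_width < 1 or self.motif_width > self.element_length:
            raise ValueError("motif_width must be in [1, element_length]")
        for name in ("effect_sd", "noise_sd", "site_strength_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")


def simulate_counts(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a barcode-level count table.

    Per barcode ``b`` of region ``r``: ``D_b ~ Gamma(shape, scale)`` and
    ``R_b ~ Poisson(alpha_r * D_b * rna_depth_factor)``. True log2 alpha is
    normal with mean 0 (inactive) or ``alpha_log2_mean`` (active) and sd
    ``alpha_log2_sd``. Controls always draw from the inactive component.

    Returns
    -------
    counts : DataFrame
        Columns ``region_id, barcode_id, dna, rna, batch, is_control``.
    truth : DataFrame
        Per region: ``region_id, alpha, log2_alpha, active, is_control``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_total = config.n_regions + config.n_controls

    width = len(str(n_total))
    region_ids = np.array(
        [f"region_{i:0{width}d}" for i in range(config.n_regions)]
        + [f"control_{i:0{width}d}" for i in range(config.n_controls)]
    )
    is_control = np.zeros(n_total, dtype=bool)
    is_control[config.n_regions :] = True

    active = np.zeros(n_total, dtype=bool)
    active[: config.n_regions] = rng.random(config.n_regions) < config.active_fraction

    log2_alpha = rng.normal(0.0, config.alpha_log2_sd, size=n_total)
    log2_alpha[active] += config.alpha_log2_mean
    alpha = 2.0**log2_alpha

    nb = config.barcodes_per_region
    dna = rng.gamma(config.dna_gamma_shape, config.dna_gamma_scale, size=(n_total, nb))
    latent = dna
    if config.barcode_effect_sd > 0:
        latent = dna * rng.lognormal(0.0, config.barcode_effect_sd, size=dna.shape)
    lam = alpha[:, None] * latent * config.rna_depth_factor
    rna = rng.poisson(lam)

    counts = pd.DataFrame(
        {
            "region_id": np.repeat(region_ids, nb),
            "barcode_id": np.tile([f"bc{j:03d}" for j in range(nb)], n_total),
            "dna": np.round(dna).astype(np.int64).ravel(),
            "rna": rna.ravel().astype(np.int64),
            "batch": "b1",
            "is_control": np.repeat(is_control, nb),
        }
    )
    truth = pd.DataFrame(
        {
            "region_id": region_ids,
            "alpha": alpha,
            "log2_alpha": log2_alpha,
            "active": active,
            "is_control": is_control,
        }
    )
    return counts, truth


def _consensus(pwm_matrix: np.ndarray) -> str:
    return "".join(NUCLEOTIDES[np.argmax(pwm_matrix, axis=1)])


def simulate_sequences(
    n: int,
    length: int,
    motifs: dict[str, np.ndarray] | None = None,
    plant_prob: float = 0.0,
    gc_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Simulate DNA sequences with optional planted motif consensus inserts.

    Parameters
    ----------
    motifs : dict of motif_id -> (positions x 4) probability matrix
        The consensus (argmax base per position) is inserted.
    plant_prob : float
        Probability a sequence receives a planted insert; planted sequences
        receive exactly one insert of one randomly chosen motif.
    gc_fraction : float
        Background GC content; bases are i.i.d.

    Returns
    -------
    records : list of (sequence_id, sequence)
    truth : DataFrame with columns ``seq_id, motif_id, start`` (0-based),
        one row per planted insert.
    """
    if n < 1 or length < 1:
        raise ValueError("n and length must be >= 1")
    motifs = motifs or {}
    for mid, mat in motifs.items():
        if mat.shape[0] > length:
            raise ValueError(
                f"motif {mid!r} (length {mat.shape[0]}) is longer than sequence length {length}"
            )
    rng = np.random.default_rng(seed)
    p = np.array(
        [
            (1 - gc_fraction) / 2,
            gc_fraction / 2,
            gc_fraction / 2,
            (1 - gc_fraction) / 2,
        ]
    )
    motif_ids = sorted(motifs)
    records: list[tuple[str, str]] = []
    rows = []
    width = len(str(n))
    for i in range(n):
        seq = rng.choice(NUCLEOTIDES, size=length, p=p)
        sid = f"seq_{i:0{width}d}"
        if motif_ids and rng.random() < plant_prob:
            mid = motif_ids[rng.integers(len(motif_ids))]
            cons = _consensus(motifs[mid])
            start = int(rng.integers(0, length - len(cons) + 1))
            seq[start : start + len(cons)] = list(cons)
            rows.append({"seq_id": sid, "motif_id": mid, "start": start})
        records.append((sid, "".join(seq)))
    truth = pd.DataFrame(rows, columns=["seq_id", "motif_id", "start"])
    return records, truth


def simulate_paired_datasets(
    config: PairedSimConfig,
) -> tuple[
    tuple[pd.DataFrame, pd.Series, pd.Series],
    tuple[pd.DataFrame, pd.Series, pd.Series],
]:
    """Two datasets over identical regions with shared + specific activity.

    ``activity_d = X_shared @ beta_shared + X_specific_d @ beta_d + noise``;
    binary labels threshold each dataset's activity at its upper
    ``active_fraction`` quantile. Region ids are identical and identically
    ordered in both outputs. Feature matrices expose the shared block plus
    both specific blocks (so the two datasets share a feature namespace);
    dataset A's activity does not depend on B's specific block and vice
    versa.
    """
    config.validate()
    rng = np.random.default_rng(config.base.seed)
    n = config.base.n_regions
    width = len(str(n))
    ids = pd.Index([f"region_{i:0{width}d}" for i in range(n)], name="region_id")

    ks, kd = config.shared_feature_count, config.specific_feature_count
    x_shared = rng.normal(size=(n, ks))
    x_a = rng.normal(size=(n, kd))
    x_b = rng.normal(size=(n, kd))
    beta_shared = rng.normal(0.0, config.shared_effect_sd, size=ks)
    beta_a = rng.normal(0.0, config.specific_effect_sd, size=kd)
    beta_b = rng.normal(0.0, config.specific_effect_sd, size=kd)

    base = x_shared @ beta_shared
    act_a = base + x_a @ beta_a + rng.normal(0.0, config.noise_sd, size=n)
    act_b = base + x_b @ beta_b + rng.normal(0.0, config.noise_sd, size=n)

    cols = (
        [f"shared_{j}" for j in range(ks)]
        + [f"specA_{j}" for j in range(kd)]
        + [f"specB_{j}" for j in range(kd)]
    )
    x_full = pd.DataFrame(np.hstack([x_shared, x_a, x_b]), index=ids, columns=cols)

    frac = config.base.active_fraction

    def _package(act: np.ndarray) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
        activity = pd.Series(act, index=ids, name="activity")
        if frac <= 0:
            labels = pd.Series(0, index=ids, name="active")
        else:
            cutoff = activity.quantile(1.0 - frac)
            labels = (activity > cutoff).astype(int).rename("active")
        return x_full.copy(), activity, labels

    return _package(act_a), _package(act_b)


def simulate_saturation(
    config: SatMutSimConfig,
    element_seq: str | None = None,
    element_id: str = "element_0",
    element_class: str = "enhancer",
) -> tuple[pd.DataFrame, str]:
    """Enumerate all 3*L single-nucleotide substitutions of an element.

    Additive per-position effects derive from planted binding sites (see
    :class:`SatMutSimConfig`): substitutions inside a site change the motif's
    log-odds score, substitutions outside any site have exactly zero effect.
    The observed continuous effect adds ``Normal(0, noise_sd)`` measurement
    noise; the discrete class is the sign of the *noiseless* effect when its
    magnitude exceeds ``class_threshold``, else 0, so the ground truth is
    unambiguous. A seeded random ``train_fraction`` of variants is marked
    ``train``; the rest ``test``.

    Returns the variant table and the (possibly generated) wild-type sequence.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.element_length
    if element_seq is None:
        seq_arr = rng.choice(NUCLEOTIDES, size=L)
    else:
        if len(element_seq) != L:
            raise ValueError(
                f"element_seq length {len(element_seq)} != element_length {L}"
            )
        seq_arr = np.array(list(element_seq))

    # motif with variable per-position sharpness; log-odds vs uniform background
    w = config.motif_width
    pwm = rng.dirichlet(np.full(4, 0.3), size=w)
    log_odds = np.log2(np.maximum(pwm, 1e-3) / 0.25)
    consensus = np.argmax(pwm, axis=1)

    n_sites = int(round(config.effect_sparsity * L / w))
    occupied = np.zeros(L, dtype=bool)
    site_starts: list[int] = []
    attempts = 0
    while len(site_starts) < n_sites and attempts < 50 * max(n_sites, 1):
        s = int(rng.integers(0, L - w + 1))
        attempts += 1
        if not occupied[s : s + w].any():
            site_starts.append(s)
            occupied[s : s + w] = True
            seq_arr[s : s + w] = NUCLEOTIDES[consensus]
    site_strength = np.abs(rng.normal(1.0, config.site_strength_sd, size=len(site_starts)))
    element_seq = "".join(seq_arr)

    nuc_index = {c: i for i, c in enumerate(NUCLEOTIDES)}
    effect_map = np.zeros((L, 4))
    for s, strength in zip(site_starts, site_strength):
        for off in range(w):
            pos = s + off
            ref_i = nuc_index[element_seq[pos]]
            effect_map[pos, :] += strength * (log_odds[off] - log_odds[off, ref_i])
    nz = effect_map[effect_map != 0]
    if nz.size and nz.std() > 0:
        effect_map *= config.effect_sd / nz.std()

    rows = []
    for pos in range(L):
        ref = element_seq[pos]
        for alt_idx, alt in enumerate(NUCLEOTIDES):
            if alt == ref:
                continue
            true_eff = effect_map[pos, alt_idx]
            observed = true_eff + rng.normal(0.0, config.noise_sd)
            if abs(true_eff) > config.class_threshold:
                cls = int(np.sign(true_eff))
            else:
                cls = 0
            rows.append(
                {
                    "element_id": element_id,
                    "element_class": element_class,
                    "position": pos,
                    "ref": ref,
                    "alt": alt,
                    "continuous_effect": observed,
                    "discrete_class": cls,
                }
            )
    table = pd.DataFrame(rows)
    n_var = len(table)
    n_train = int(round(config.train_fraction * n_var))
    train_idx = rng.choice(n_var, size=n_train, replace=False)
    split = np.full(n_var, "test", dtype=object)
    split[train_idx] = "train"
    table["split"] = split
    return table, element_seq
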