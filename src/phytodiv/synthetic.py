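"""Synthetic feature tables and fragmentation-spectrum libraries.

Emulates the sampling design and statistical structure of an organ-level
comparative-metabolomics survey: ``n_species`` species, each sampled from
``n_plants_per_species`` individual plants, each plant contributing one
sample per organ (leaf, seed, unripe pulp, ripe pulp).  Compounds fall into
four occurrence pools — a large shared core, fruit-specific, leaf-specific
and species-specific — and fruit organs carry inflated sample-to-sample
presence noise so that fruit beta-dispersion exceeds leaf beta-dispersion.

Spectra are generated in structural "classes": spectra within a class share
a backbone of fragment peaks (with class-level intensities), so spectral
cosine similarity is high within a class and near zero between classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from phytodiv.occurrence import ORGANS, FRUIT_ORGANS, FeatureTable
from phytodiv.spectra import FragmentationSpectrum, SpectralLibrary

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate_dataset",
           "generate_spectra_library", "write_truth"]

# stable sub-stream labels: adding a compound pool or a new consumer must
# not shift the noise draws of existing stages
_STREAMS = ("core", "fruit", "leaf", "species", "noise", "classes", "spectra")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study design.

    Defaults mirror the scale of a 12-species survey with ~1,300 binary
    features, a dominant shared core, more fruit-specific than leaf-specific
    compounds, species effects dominating organ effects, and noisier fruit
    organs than leaves.
    """

    n_species: int = 12
    n_plants_per_species: int = 3
    organs: tuple[str, ...] = ORGANS
    n_core_compounds: int = 1126
    n_fruit_specific: int = 92
    n_leaf_specific: int = 4
    n_species_specific_per_species: int = 7
    p_core_present: float = 0.9
    organ_effect: float = 0.8
    noise_rate: float = 0.02
    fruit_beta_inflation: float = 2.0
    n_structural_classes: int = 20
    peaks_per_spectrum: tuple[int, int] = (8, 15)
    shared_backbone_fraction: float = 0.6
    mz_range: tuple[float, float] = (50.0, 500.0)
    seed: int = 0

    def __post_init__(self) -> None:
        counts = dict(
            n_species=self.n_species,
            n_plants_per_species=self.n_plants_per_species,
            n_core_compounds=self.n_core_compounds,
            n_structural_classes=self.n_structural_classes,
        )
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        for name in ("n_fruit_specific", "n_leaf_specific",
                     "n_species_specific_per_species"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("p_core_present", "organ_effect", "noise_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.fruit_beta_inflation < 1.0:
            raise ValueError("fruit_beta_inflation must be >= 1")
        if not self.organs or len(set(self.organs)) != len(self.organs):
            raise ValueError("organs must be non-empty with unique labels")
        unknown = set(self.organs) - set(ORGANS)
        if unknown:
            raise ValueError(f"unknown organ labels: {sorted(unknown)}")
        lo, hi = self.peaks_per_spectrum
        if lo < 1 or hi < lo:
            raise ValueError("peaks_per_spectrum must be a range with 1 <= lo <= hi")
        if not 0.0 <= self.shared_backbone_fraction <= 1.0:
            raise ValueError("shared_backbone_fraction must be in [0, 1]")
        if self.mz_range[0] <= 0 or self.mz_range[1] <= self.mz_range[0]:
            raise ValueError("mz_range must be a positive, increasing Da interval")

    @property
    def n_compounds(self) -> int:
        return (self.n_core_compounds + self.n_fruit_specific
                + self.n_leaf_specific
                + self.n_species * self.n_species_specific_per_species)

    def rng(self, stream: str) -> np.random.Generator:
        """Independent generator for one named sub-stream of ``seed``."""
        idx = _STREAMS.index(stream)
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(idx,)))


@dataclass
class SyntheticTruth:
    """Ground truth behind a synthetic dataset.

    ``compound_organ_class`` assigns each compound its occurrence pool
    (core / fruit_specific / leaf_specific / species_specific);
    ``compound_structural_class`` its spectral class id;
    ``informative_features`` the compounds that carry organ signal
    (the fruit- and leaf-specific pools).
    """

    compound_organ_class: dict[str, str]
    compound_structural_class: dict[str, int]
    informative_features: set[str] = field(default_factory=set)

    def validate_against(self, compound_ids: list[str]) -> None:
        ids = set(compound_ids)
        if set(self.compound_organ_class) != ids:
            raise ValueError("compound_organ_class does not cover the table exactly")
        if set(self.compound_structural_class) != ids:
            raise ValueError("compound_structural_class does not cover the table exactly")


def _compound_ids(config: SyntheticConfig) -> tuple[list[str], dict[str, str]]:
    ids: list[str] = []
    pool: dict[str, str] = {}
    for i in range(config.n_core_compounds):
        cid = f"core{i + 1:04d}"
        ids.append(cid)
        pool[cid] = "core"
    for i in range(config.n_fruit_specific):
        cid = f"fruit{i + 1:04d}"
        ids.append(cid)
        pool[cid] = "fruit_specific"
    for i in range(config.n_leaf_specific):
        cid = f"leaf{i + 1:04d}"
        ids.append(cid)
        pool[cid] = "leaf_specific"
    for s in range(config.n_species):
        for i in range(config.n_species_specific_per_species):
            cid = f"sp{s + 1:02d}spec{i + 1:03d}"
            ids.append(cid)
            pool[cid] = "species_specific"
    return ids, pool


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[FeatureTable, SpectralLibrary, SyntheticTruth]:
    """Generate a feature table, spectral library and ground truth.

    The table has one row per species x plant x organ.  Core compounds are
    gated per species with probability ``p_core_present`` (all of a species'
    samples then share them, giving species effects that dominate organ
    effects); fruit-specific compounds occur only in fruit-organ rows with
    probability ``organ_effect``; leaf-specific only in leaf rows;
    species-specific only in that species' rows.  Finally each cell is
    bit-flipped with probability ``noise_rate`` (times
    ``fruit_beta_inflation`` in fruit organs).  Fully reproducible from
    ``config.seed``.
    """
    compound_ids, pool = _compound_ids(config)
    if config.n_compounds != len(compound_ids):  # defensive; pools define the total
        raise ValueError("specific pools inconsistent with total compound count")

    organs = list(config.organs)
    rows = []
    for s in range(config.n_species):
        species = f"sp{s + 1:02d}"
        for p in range(config.n_plants_per_species):
            plant = f"{species}_p{p + 1}"
            for organ in organs:
                rows.append((f"{species}_{plant.split('_')[1]}_{organ}",
                             species, plant, organ))
    meta = pd.DataFrame(rows, columns=["sample_id", "species", "plant", "organ"])
    meta = meta.set_index("sample_id")
    n_samples = len(meta)

    presence = np.zeros((n_samples, len(compound_ids)), dtype=np.int8)
    col = {cid: j for j, cid in enumerate(compound_ids)}
    species_of = meta["species"].to_numpy()
    organ_of = meta["organ"].to_numpy()
    is_fruit_row = np.isin(organ_of, list(FRUIT_ORGANS))
    is_leaf_row = organ_of == "leaf"

    # core: species-level occupancy, shared by all of that species' samples
    rng = config.rng("core")
    core_gate = rng.random((config.n_species, config.n_core_compounds)) < config.p_core_present
    species_labels = [f"sp{s + 1:02d}" for s in range(config.n_species)]
    species_index = {sp: s for s, sp in enumerate(species_labels)}
    core_cols = [col[c] for c in compound_ids if pool[c] == "core"]
    for i in range(n_samples):
        presence[i, core_cols] = core_gate[species_index[species_of[i]]]

    # rng.random() is on [0, 1), so organ_effect == 1 yields certain presence
    rng = config.rng("fruit")
    fruit_cols = [col[c] for c in compound_ids if pool[c] == "fruit_specific"]
    if fruit_cols:
        draws = rng.random((int(is_fruit_row.sum()), len(fruit_cols)))
        presence[np.ix_(np.flatnonzero(is_fruit_row), fruit_cols)] = (
            draws < config.organ_effect)

    rng = config.rng("leaf")
    leaf_cols = [col[c] for c in compound_ids if pool[c] == "leaf_specific"]
    if leaf_cols:
        draws = rng.random((int(is_leaf_row.sum()), len(leaf_cols)))
        presence[np.ix_(np.flatnonzero(is_leaf_row), leaf_cols)] = (
            draws < config.organ_effect)

    rng = config.rng("species")
    for s, sp in enumerate(species_labels):
        sp_cols = [col[c] for c in compound_ids
                   if pool[c] == "species_specific" and c.startswith(f"sp{s + 1:02d}spec")]
        if not sp_cols:
            continue
        rows_sp = np.flatnonzero(species_of == sp)
        draws = rng.random((len(rows_sp), len(sp_cols)))
        presence[np.ix_(rows_sp, sp_cols)] = draws < config.organ_effect

    # symmetric bit-flip noise, organ-specific rate
    rng = config.rng("noise")
    rate = np.where(is_fruit_row,
                    min(1.0, config.noise_rate * config.fruit_beta_inflation),
                    config.noise_rate)
    flips = rng.random(presence.shape) < rate[:, None]
    presence = presence ^ flips.astype(np.int8)

    table = FeatureTable(
        presence=pd.DataFrame(presence, index=meta.index, columns=compound_ids),
        metadata=meta,
    )

    rng = config.rng("classes")
    structural_class = {
        cid: int(k) for cid, k in zip(
            compound_ids,
            rng.integers(0, config.n_structural_classes, len(compound_ids)))
    }
    truth = SyntheticTruth(
        compound_organ_class=dict(pool),
        compound_structural_class=structural_class,
        informative_features={c for c, p in pool.items()
                              if p in ("fruit_specific", "leaf_specific")},
    )
    truth.validate_against(compound_ids)
    library = generate_spectra_library(config, truth)
    return table, library, truth


def generate_spectra_library(
    config: SyntheticConfig, truth: SyntheticTruth
) -> SpectralLibrary:
    """Generate one spectrum per compound from its structural class.

    Each class owns a backbone pool of fragment m/z values with class-level
    intensities.  A compound's spectrum draws
    ``round(shared_backbone_fraction * n_peaks)`` peaks from that pool
    (keeping the shared intensities) and fills the rest with
    compound-unique peaks, so expected within-class cosine exceeds
    between-class cosine.  With ``shared_backbone_fraction == 1`` every
    compound in a class gets the identical full backbone.
    """
    rng = config.rng("spectra")
    lo, hi = config.peaks_per_spectrum
    mz_lo, mz_hi = config.mz_range

    backbone_mz: dict[int, np.ndarray] = {}
    backbone_int: dict[int, np.ndarray] = {}
    for k in range(config.n_structural_classes):
        mz = np.sort(rng.uniform(mz_lo, mz_hi, hi))
        inten = rng.uniform(0.0, 1.0, hi)
        inten[inten == 0.0] = 1.0  # intensities on (0, 1]
        backbone_mz[k] = mz
        backbone_int[k] = inten

    spectra: dict[str, FragmentationSpectrum] = {}
    for cid in sorted(truth.compound_structural_class):
        k = truth.compound_structural_class[cid]
        if config.shared_backbone_fraction >= 1.0:
            mzs, intens = backbone_mz[k].copy(), backbone_int[k].copy()
        else:
            n_peaks = int(rng.integers(lo, hi + 1))
            n_shared = int(round(config.shared_backbone_fraction * n_peaks))
            idx = rng.choice(hi, size=n_shared, replace=False) if n_shared else np.array([], int)
            n_unique = n_peaks - n_shared
            umz = rng.uniform(mz_lo, mz_hi, n_unique)
            uint = rng.uniform(0.0, 1.0, n_unique)
            uint[uint == 0.0] = 1.0
            mzs = np.concatenate([backbone_mz[k][idx], umz])
            intens = np.concatenate([backbone_int[k][idx], uint])
        intens = intens / intens.max() * 100.0  # cosine is scale-invariant
        precursor = float(rng.uniform(mz_hi, mz_hi + 300.0))
        spectra[cid] = FragmentationSpectrum(
            compound_id=cid, precursor_mz=precursor,
            mz=np.asarray(mzs, float), intensity=np.asarray(intens, float))
    return SpectralLibrary(spectra=spectra)


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Serialize ground truth as JSON (sets become sorted lists)."""
    payload = {
        "compound_organ_class": dict(sorted(truth.compound_organ_class.items())),
        "compound_structural_class": dict(sorted(truth.compound_structural_class.items())),
        "informative_features": sorted(truth.informative_features),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def config_to_dict(config: SyntheticConfig) -> dict:
    return asdict(config)
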