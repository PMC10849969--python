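"""Synthetic spectra, repository corpora, and abundance tables.

This module is the test substrate for the rest of the toolkit. It produces

* rule-based reference MS/MS spectra for condensation products (precursor
  ion, sequential water losses — three for trihydroxylated and two for
  dihydroxylated bile cores — and the amide/ester bond-cleavage ions:
  the protonated amine / amino-acid / hydroxy-acid fragment and the
  acylium ion of the acyl partner, each optionally minus water);
* noisy desk-scale "repositories": per-sample-file MGF corpora in which
  each compound occurs with a phenotype-dependent probability, plus
  fragment-scrambled decoy spectra, ReDU-style sample metadata, and an
  exact ground-truth ledger of what was planted where;
* log-normal abundance tables with a group-specific location shift for
  enriched compounds, zeros where a compound is absent.

Fragment relative intensities default to uniform — the rule set models
which ions appear, not their branching ratios. Every output is a pure
function of (seed, config); each sample file draws from its own RNG stream
derived from the master seed by stable hashing, so files are reproducible
independently of generation order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chemlib import (
    WATER,
    BuildingBlock,
    CompoundRecord,
    MONOISOTOPIC_MASS,
    Adduct,
    adduct_mz,
    get_adduct,
    monoisotopic_mass,
)
from ._elements import ELECTRON_MASS, PROTON_MASS
from .spectra import Spectrum

__all__ = [
    "FragmentationTemplate",
    "SimConfig",
    "SimGroundTruth",
    "default_template",
    "theoretical_spectrum",
    "perturb_spectrum",
    "simulate_repository",
    "simulate_abundance_table",
]

_WATER_MASS = monoisotopic_mass(WATER)
# RCOOH -> RCO+ + OH-; the acylium m/z is the neutral acid minus hydroxide.
_HYDROXIDE_MASS = MONOISOTOPIC_MASS["O"] + MONOISOTOPIC_MASS["H"] + ELECTRON_MASS


@dataclass(frozen=True)
class FragmentationTemplate:
    """Rule-based fragment list for a compound class.

    Each rule is ``(name, relative_intensity)`` where the name selects a
    formula transform: ``precursor``, ``water_loss:k``, ``right+H``,
    ``right+H-H2O``, ``acylium`` and ``acylium-H2O``.
    """

    compound_class: str
    rules: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError("fragmentation template has no rules")
        if len(self.rules) < 6:
            raise ValueError(
                "template must yield >= 6 fragments so matches can reach the "
                "minimum matched-ion count")


_BASE_RULES = ("right+H", "right+H-H2O", "acylium", "acylium-H2O")


def default_template(compound_class: str) -> FragmentationTemplate:
    """Default template per class; water-loss depth follows hydroxyl count."""
    n_water = {"amide": 1, "ester": 1, "bile_amidate_di": 2, "bile_amidate_tri": 3}
    if compound_class not in n_water:
        raise KeyError(f"unknown compound class {compound_class!r}")
    names = ["precursor"]
    names += [f"water_loss:{k}" for k in range(1, n_water[compound_class] + 1)]
    names += list(_BASE_RULES)
    return FragmentationTemplate(compound_class, tuple((n, 1.0) for n in names))


def template_class_for(record: CompoundRecord) -> str:
    """Map a library record to its fragmentation-template class."""
    if record.rule in ("amide", "ester"):
        return record.rule
    if record.rule == "bile_amidate":
        n_oxygen = record.formula.element_counts.get("O", 0)
        # bile amidate: steroid hydroxyls + amide O + amino-acid oxygens
        # resolve via the bile core: tri cores carry one more oxygen
        return "bile_amidate_tri" if n_oxygen >= 6 else "bile_amidate_di"
    raise KeyError(f"no template class for rule {record.rule!r}")


def _fragment_mz(
    rule_name: str,
    precursor_mz: float,
    left: BuildingBlock,
    right: BuildingBlock,
) -> float:
    if rule_name == "precursor":
        return precursor_mz
    if rule_name.startswith("water_loss:"):
        k = int(rule_name.split(":", 1)[1])
        return precursor_mz - k * _WATER_MASS
    if rule_name == "right+H":
        return monoisotopic_mass(right.formula) + PROTON_MASS
    if rule_name == "right+H-H2O":
        return monoisotopic_mass(right.formula) + PROTON_MASS - _WATER_MASS
    if rule_name == "acylium":
        return monoisotopic_mass(left.formula) - _HYDROXIDE_MASS
    if rule_name == "acylium-H2O":
        return monoisotopic_mass(left.formula) - _HYDROXIDE_MASS - _WATER_MASS
    raise KeyError(f"unknown fragment rule {rule_name!r}")


def theoretical_spectrum(
    record: CompoundRecord,
    template: FragmentationTemplate,
    adduct: Adduct,
    blocks: Mapping[str, BuildingBlock],
) -> Spectrum:
    """Deterministic rule-based reference spectrum for a library compound."""
    expected = template_class_for(record)
    if template.compound_class != expected:
        raise ValueError(
            f"record {record.compound_id} needs template class {expected!r}, "
            f"got {template.compound_class!r}")
    left = blocks[record.left_block]
    right = blocks[record.right_block]
    precursor = adduct_mz(record.monoisotopic_mass, adduct)
    mzs, intensities = [], []
    for rule_name, rel in template.rules:
        mz = _fragment_mz(rule_name, precursor, left, right)
        if mz <= 0:
            raise ValueError(
                f"fragment rule {rule_name!r} yields non-positive m/z "
                f"({mz:.4f}) for {record.compound_id}")
        mzs.append(mz)
        intensities.append(rel)
    return Spectrum(
        spectrum_id=f"{record.compound_id}|{adduct.name}",
        precursor_mz=precursor,
        precursor_intensity=1.0,
        charge=adduct.charge,
        mz=np.array(mzs),
        intensities=np.array(intensities, dtype=float),
        ms_level=2,
    )


@dataclass(frozen=True)
class SimConfig:
    """Simulator conditions.

    Defaults encode the planted-enrichment study design: two phenotype
    groups of 100 sample files, enriched compounds occurring in half of the
    case-group files against a 5% background, Q-ToF-scale noise, and five
    decoy spectra per file.
    """

    seed: int = 0
    n_files_per_group: int = 100
    group_labels: tuple[str, ...] = ("CD", "nonIBD")
    baseline_probability: float = 0.05
    enriched_probability: float = 0.5
    enriched_compounds: tuple[str, ...] = ()
    enriched_group: str = "CD"
    occurrence_overrides: Mapping[tuple[str, str], float] = field(default_factory=dict)
    mz_jitter_sd: float = 0.002
    intensity_cv: float = 0.2
    peak_dropout_prob: float = 0.05
    n_decoys: int = 5
    instrument_tag: str = "qtof"
    adduct_name: str = "[M+H]+"
    min_surviving_peaks: int = 6
    abundance_shift: float = 1.0
    abundance_mu: float = 5.0
    abundance_sigma: float = 1.0

    def __post_init__(self) -> None:
        for p in (self.baseline_probability, self.enriched_probability,
                  *self.occurrence_overrides.values()):
            if not 0 <= p <= 1:
                raise ValueError(f"occurrence probability {p} outside [0, 1]")
        if min(self.mz_jitter_sd, self.intensity_cv, self.peak_dropout_prob) < 0:
            raise ValueError("noise parameters must be >= 0")

    def occurrence_probability(self, group: str, compound_id: str) -> float:
        override = self.occurrence_overrides.get((group, compound_id))
        if override is not None:
            return override
        if group == self.enriched_group and compound_id in self.enriched_compounds:
            return self.enriched_probability
        return self.baseline_probability


@dataclass
class SimGroundTruth:
    """Exact ledger of what the simulator planted."""

    seed: int
    planted: dict[str, list[str]]  # file -> compound ids
    decoys: dict[str, list[str]]  # file -> decoy spectrum ids
    group_of_file: dict[str, str]
    occurrence_probability: dict[tuple[str, str], float]  # (group, compound) -> p
    compound_ids: tuple[str, ...]

    @property
    def n_planted(self) -> int:
        return sum(len(v) for v in self.planted.values())

    @property
    def n_decoys(self) -> int:
        return sum(len(v) for v in self.decoys.values())


def _file_rng(seed: int, file_name: str) -> np.random.Generator:
    # stable per-file stream: master seed + CRC32 of the file name
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(file_name.encode())]))


def perturb_spectrum(
    s: Spectrum,
    rng: np.random.Generator,
    mz_jitter_sd: float = 0.0,
    intensity_cv: float = 0.0,
    peak_dropout_prob: float = 0.0,
    min_surviving_peaks: int = 6,
) -> Spectrum:
    """Instrument-noise model: Gaussian m/z jitter, multiplicative
    log-normal intensity noise, and Bernoulli peak dropout.

    Dropout never leaves fewer than ``min_surviving_peaks`` peaks (or all
    peaks, if the spectrum is smaller than that), so a planted spectrum
    stays matchable in principle. With all noise parameters zero this is
    the identity.
    """
    n = s.n_peaks
    mz = s.mz + rng.normal(0.0, mz_jitter_sd, size=n) if mz_jitter_sd > 0 else s.mz.copy()
    if intensity_cv > 0:
        sigma = float(np.sqrt(np.log1p(intensity_cv**2)))
        factors = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=n)
        intensities = s.intensities * factors
    else:
        intensities = s.intensities.copy()
    keep = np.ones(n, dtype=bool)
    if peak_dropout_prob > 0:
        keep = rng.random(n) >= peak_dropout_prob
        floor = min(min_surviving_peaks, n)
        if keep.sum() < floor:
            keep[:] = False
            keep[rng.choice(n, size=floor, replace=False)] = True
    prec_mz = s.precursor_mz
    if prec_mz is not None and mz_jitter_sd > 0:
        prec_mz = prec_mz + float(rng.normal(0.0, mz_jitter_sd))
    prec_int = s.precursor_intensity
    if prec_int is not None and intensity_cv > 0:
        sigma = float(np.sqrt(np.log1p(intensity_cv**2)))
        prec_int = prec_int * float(rng.lognormal(-sigma**2 / 2, sigma))
    return s.replace(
        mz=mz[keep], intensities=intensities[keep],
        precursor_mz=prec_mz, precursor_intensity=prec_int,
    )


def _decoy_spectrum(
    base: Spectrum, rng: np.random.Generator, decoy_id: str
) -> Spectrum:
    """Fragment-scrambled negative control with the precursor retained.

    Keeps the peak count, intensities and precursor of a real library
    spectrum — so the decoy always passes the precursor filter — but
    redraws every fragment m/z uniformly below the precursor.
    """
    lo, hi = 50.0, max(base.precursor_mz - 1.0, 51.0)
    mz = rng.uniform(lo, hi, size=base.n_peaks)
    return base.replace(mz=np.sort(mz), spectrum_id=decoy_id)


def simulate_repository(
    library: Sequence[CompoundRecord],
    config: SimConfig,
    blocks: Mapping[str, BuildingBlock],
) -> tuple[dict[str, list[Spectrum]], pd.DataFrame, SimGroundTruth]:
    """Generate a per-file spectral corpus with planted compounds and decoys.

    Returns ``(corpus, metadata, ground_truth)`` where ``corpus`` maps a
    sample file name to its MS2 spectra, ``metadata`` is a ReDU-style table
    keyed by source_file, and the ground truth records every planted and
    decoy spectrum exactly once.
    """
    if not library:
        raise ValueError("library must be non-empty")
    adduct = get_adduct(config.adduct_name)
    templates = {rec.compound_id: default_template(template_class_for(rec))
                 for rec in library}
    reference = {
        rec.compound_id: theoretical_spectrum(rec, templates[rec.compound_id],
                                              adduct, blocks)
        for rec in library
    }
    corpus: dict[str, list[Spectrum]] = {}
    planted: dict[str, list[str]] = {}
    decoys: dict[str, list[str]] = {}
    group_of_file: dict[str, str] = {}
    meta_rows = []
    for group in config.group_labels:
        for i in range(config.n_files_per_group):
            fname = f"{group}_{i:04d}.mgf"
            rng = _file_rng(config.seed, fname)
            spectra: list[Spectrum] = []
            planted[fname] = []
            decoys[fname] = []
            group_of_file[fname] = group
            for rec in library:
                if rng.random() < config.occurrence_probability(group, rec.compound_id):
                    spec = perturb_spectrum(
                        reference[rec.compound_id], rng,
                        config.mz_jitter_sd, config.intensity_cv,
                        config.peak_dropout_prob, config.min_surviving_peaks,
                    ).replace(
                        source_file=fname,
                        instrument_tag=config.instrument_tag,
                        scan_number=len(spectra),
                    )
                    spectra.append(spec)
                    planted[fname].append(rec.compound_id)
            for d in range(config.n_decoys):
                base_rec = library[rng.integers(len(library))]
                decoy_id = f"decoy|{fname}|{d}"
                spec = _decoy_spectrum(reference[base_rec.compound_id], rng, decoy_id)
                spec = spec.replace(
                    source_file=fname,
                    instrument_tag=config.instrument_tag,
                    scan_number=len(spectra),
                )
                spectra.append(spec)
                decoys[fname].append(decoy_id)
            corpus[fname] = spectra
            meta_rows.append({
                "source_file": fname,
                "organism": "Homo sapiens",
                "sample_type": "feces",
                "phenotype": group,
                "dataset_id": f"SIM-{config.seed}",
            })
    metadata = pd.DataFrame(meta_rows).set_index("source_file", drop=False)
    truth = SimGroundTruth(
        seed=config.seed,
        planted=planted,
        decoys=decoys,
        group_of_file=group_of_file,
        occurrence_probability={
            (g, rec.compound_id): config.occurrence_probability(g, rec.compound_id)
            for g in config.group_labels for rec in library
        },
        compound_ids=tuple(rec.compound_id for rec in library),
    )
    return corpus, metadata, truth


def simulate_abundance_table(
    config: SimConfig,
    ground_truth: SimGroundTruth,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Compound x sample abundance table consistent with the ground truth.

    Where a compound was planted, abundance is log-normal with location
    ``abundance_mu`` plus ``abundance_shift`` for enriched compounds in the
    enriched group; where it was absent, abundance is zero.
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 0x0ABD]))
    files = list(ground_truth.planted)
    table = pd.DataFrame(0.0, index=list(ground_truth.compound_ids), columns=files)
    for fname in files:
        group = ground_truth.group_of_file[fname]
        for cid in ground_truth.planted[fname]:
            mu = config.abundance_mu
            if group == config.enriched_group and cid in config.enriched_compounds:
                mu += config.abundance_shift
            table.at[cid, fname] = float(rng.lognormal(mu, config.abundance_sigma))
    return table
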