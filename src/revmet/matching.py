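"""Spectral and feature matching.

``repository_search`` re-implements, at desk scale, the repository search
criteria used for public-data mining: candidate corpus spectra are filtered
by absolute precursor-m/z difference (0.01 Da for Orbitrap data, 0.02 Da for
Q-ToF), then scored by cosine similarity over tolerance-paired fragment
peaks; a hit requires cosine >= 0.7 and at least 6 matched fragment ions.
These thresholds were chosen upstream to keep the spectral false-discovery
rate below about 1%.

Peak intensities are square-root scaled and L2-normalized before the dot
product (the convention of GNPS-style spectral matching), which makes the
score scale-invariant and bounded in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chemlib import ppm_error
from .spectra import Spectrum

__all__ = [
    "MatchCriteria",
    "SpectralMatch",
    "FeatureMatchCriteria",
    "Feature",
    "FeatureMatchResult",
    "pair_peaks",
    "cosine_score",
    "repository_search",
    "matches_to_frame",
    "isotope_dot_product",
    "feature_library_match",
]

#: Default precursor tolerance (Da) per instrument class.
PRECURSOR_TOL = {"orbitrap": 0.01, "qtof": 0.02}


@dataclass(frozen=True)
class MatchCriteria:
    """Repository-search acceptance thresholds."""

    precursor_tol: float = 0.02
    fragment_tol: float = 0.02
    min_matched_ions: int = 6
    min_cosine: float = 0.7

    def __post_init__(self) -> None:
        if self.precursor_tol <= 0 or self.fragment_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.min_matched_ions < 1:
            raise ValueError("min_matched_ions must be >= 1")

    @classmethod
    def for_instrument(cls, instrument: str, **kwargs) -> "MatchCriteria":
        tol = PRECURSOR_TOL.get(instrument.lower())
        if tol is None:
            raise ValueError(f"unknown instrument class {instrument!r}")
        kwargs.setdefault("precursor_tol", tol)
        kwargs.setdefault("fragment_tol", tol)
        return cls(**kwargs)


@dataclass(frozen=True)
class SpectralMatch:
    """A criteria-passing query <-> corpus hit."""

    query_id: str
    corpus_spectrum_id: str
    source_file: str
    cosine: float
    n_matched_ions: int
    precursor_delta: float


def pair_peaks(
    query: Spectrum, target: Spectrum, fragment_tol: float
) -> list[tuple[int, int]]:
    """One-to-one fragment pairing within an m/z tolerance.

    Candidate pairs (|dmz| <= tol) are accepted greedily by descending
    intensity product, breaking ties toward the lower query m/z, then the
    lower target m/z; each peak is used at most once. Returns (query index,
    target index) pairs sorted by query index.
    """
    qmz, tmz = query.mz, target.mz
    if qmz.size == 0 or tmz.size == 0:
        return []
    lo = np.searchsorted(tmz, qmz - fragment_tol, side="left")
    hi = np.searchsorted(tmz, qmz + fragment_tol, side="right")
    cand = [
        (-(query.intensities[i] * target.intensities[j]), qmz[i], tmz[j], i, j)
        for i in range(qmz.size)
        for j in range(lo[i], hi[i])
    ]
    cand.sort(key=lambda t: t[:3])
    used_q: set[int] = set()
    used_t: set[int] = set()
    pairs = []
    for _, _, _, i, j in cand:
        if i in used_q or j in used_t:
            continue
        used_q.add(i)
        used_t.add(j)
        pairs.append((i, j))
    pairs.sort()
    return pairs


def cosine_score(
    query: Spectrum, target: Spectrum, fragment_tol: float
) -> tuple[float, int]:
    """Cosine similarity over tolerance-paired peaks.

    Intensities are square-root scaled; the dot product over paired peaks is
    normalized by the full-spectrum L2 norms, so unmatched peaks penalize
    the score. Returns (cosine, number of matched ions).
    """
    if query.n_peaks == 0 or target.n_peaks == 0:
        raise ValueError("cosine_score requires non-empty spectra")
    pairs = pair_peaks(query, target, fragment_tol)
    if not pairs:
        return 0.0, 0
    qs = np.sqrt(query.intensities)
    ts = np.sqrt(target.intensities)
    qi, ti = zip(*pairs)
    dot = float(np.sum(qs[list(qi)] * ts[list(ti)]))
    denom = float(np.linalg.norm(qs) * np.linalg.norm(ts))
    if denom == 0:
        raise ValueError("cosine undefined for all-zero intensities")
    return min(dot / denom, 1.0), len(pairs)


def repository_search(
    queries: Sequence[Spectrum],
    corpus: Sequence[Spectrum],
    criteria: MatchCriteria = MatchCriteria(),
) -> tuple[list[SpectralMatch], dict[str, int]]:
    """Search query spectra against a corpus with repository-style criteria.

    For each query, corpus MS2 spectra within ``precursor_tol`` of the query
    precursor are scored; hits meeting ``min_cosine`` and
    ``min_matched_ions`` are returned, together with the per-query count of
    distinct source files among its hits.
    """
    corpus_ms2 = [s for s in corpus if s.ms_level == 2 and s.precursor_mz is not None]
    prec = np.array([s.precursor_mz for s in corpus_ms2])
    order = np.argsort(prec)
    prec_sorted = prec[order]
    matches: list[SpectralMatch] = []
    file_counts: dict[str, int] = {}
    for q in queries:
        if q.precursor_mz is None:
            raise ValueError(f"query {q.spectrum_id!r} lacks a precursor m/z")
        files: set[str] = set()
        lo = np.searchsorted(prec_sorted, q.precursor_mz - criteria.precursor_tol, "left")
        hi = np.searchsorted(prec_sorted, q.precursor_mz + criteria.precursor_tol, "right")
        for k in order[lo:hi]:
            cand = corpus_ms2[k]
            cos, n_ions = cosine_score(q, cand, criteria.fragment_tol)
            if cos >= criteria.min_cosine and n_ions >= criteria.min_matched_ions:
                matches.append(SpectralMatch(
                    query_id=q.spectrum_id,
                    corpus_spectrum_id=cand.spectrum_id,
                    source_file=cand.source_file,
                    cosine=cos,
                    n_matched_ions=n_ions,
                    precursor_delta=cand.precursor_mz - q.precursor_mz,
                ))
                files.add(cand.source_file)
        file_counts[q.spectrum_id] = len(files)
    return matches, file_counts


def matches_to_frame(matches: Iterable[SpectralMatch]) -> pd.DataFrame:
    cols = ["query_id", "corpus_spectrum_id", "source_file",
            "cosine", "n_matched_ions", "precursor_delta"]
    return pd.DataFrame([vars(m) for m in matches], columns=cols)


# ---------------------------------------------------------------------------
# LC-IMS multi-attribute feature matching

def isotope_dot_product(
    theoretical: Sequence[tuple[float, float]],
    observed: Sequence[tuple[float, float]],
) -> float:
    """Normalized dot product of two isotope envelopes (idotp).

    Envelopes are aligned by isotopologue index (A, A+1, ...) and truncated
    to the common length.
    """
    if not len(theoretical) or not len(observed):
        raise ValueError("idotp requires non-empty envelopes")
    n = min(len(theoretical), len(observed))
    t = np.array([a for _, a in theoretical[:n]], dtype=float)
    o = np.array([a for _, a in observed[:n]], dtype=float)
    nt, no = np.linalg.norm(t), np.linalg.norm(o)
    if nt == 0 or no == 0:
        raise ValueError("idotp undefined for a zero-norm envelope")
    return float(np.dot(t, o) / (nt * no))


@dataclass(frozen=True)
class FeatureMatchCriteria:
    """Multi-attribute acceptance thresholds for LC-IMS library matching."""

    ppm_tol: float = 10.0
    rt_tol: float = 0.1
    ims_resolving_power: float = 40.0
    min_idotp: float = 0.8

    def __post_init__(self) -> None:
        if min(self.ppm_tol, self.rt_tol, self.ims_resolving_power, self.min_idotp) <= 0:
            raise ValueError("all criteria must be positive")
        if self.min_idotp > 1:
            raise ValueError("min_idotp must be <= 1")


@dataclass(frozen=True)
class Feature:
    """An LC(-IMS) feature: m/z, retention time, optional drift/envelope."""

    mz: float
    rt: float
    drift_time: float | None = None
    observed_envelope: Sequence[tuple[float, float]] | None = None
    intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.mz <= 0 or self.rt < 0:
            raise ValueError("feature requires mz > 0 and rt >= 0")


@dataclass(frozen=True)
class FeatureMatchResult:
    is_match: bool
    ppm: float
    ppm_ok: bool
    delta_rt: float
    rt_ok: bool
    delta_drift: float | None
    drift_window: float | None
    drift_ok: bool | None  # None => drift test skipped (missing data)
    idotp: float | None
    idotp_ok: bool | None  # None => envelope absent, test skipped
    flags: tuple[str, ...] = field(default=())


def feature_library_match(
    feature: Feature,
    theoretical_mz: float,
    reference_rt: float,
    reference_drift: float | None,
    theoretical_envelope: Sequence[tuple[float, float]] | None,
    criteria: FeatureMatchCriteria = FeatureMatchCriteria(),
) -> FeatureMatchResult:
    """Skyline-style multi-attribute library match decision.

    A feature matches a library record iff mass accuracy is within
    ``ppm_tol``, RT within ``rt_tol`` minutes, drift time within the
    half-window ``reference_drift / (2 * Rp)`` implied by the stated IMS
    resolving power (FWHM interpretation), and — when an observed envelope
    exists — idotp strictly exceeds ``min_idotp``. A feature without a
    drift time when the record has one skips the drift test with a flag
    rather than failing.
    """
    flags: list[str] = []
    ppm = ppm_error(feature.mz, theoretical_mz)
    ppm_ok = abs(ppm) <= criteria.ppm_tol
    delta_rt = feature.rt - reference_rt
    rt_ok = abs(delta_rt) <= criteria.rt_tol

    delta_drift = drift_window = None
    drift_ok: bool | None = True
    if reference_drift is None:
        drift_ok = None
        flags.append("no_reference_drift")
    elif feature.drift_time is None:
        drift_ok = None
        flags.append("drift_test_skipped_missing_feature_drift")
    else:
        drift_window = reference_drift / (2.0 * criteria.ims_resolving_power)
        delta_drift = feature.drift_time - reference_drift
        drift_ok = abs(delta_drift) <= drift_window

    idotp = None
    idotp_ok: bool | None = True
    if theoretical_envelope is None or feature.observed_envelope is None:
        idotp_ok = None
        flags.append("idotp_test_skipped_missing_envelope")
    else:
        idotp = isotope_dot_product(theoretical_envelope, feature.observed_envelope)
        idotp_ok = idotp > criteria.min_idotp

    is_match = (ppm_ok and rt_ok
                and (drift_ok is None or drift_ok)
                and (idotp_ok is None or idotp_ok))
    return FeatureMatchResult(
        is_match=is_match, ppm=ppm, ppm_ok=ppm_ok,
        delta_rt=delta_rt, rt_ok=rt_ok,
        delta_drift=delta_drift, drift_window=drift_window, drift_ok=drift_ok,
        idotp=idotp, idotp_ok=idotp_ok, flags=tuple(flags),
    )
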