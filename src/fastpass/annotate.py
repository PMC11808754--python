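"""Formula-based feature annotation.

Computes theoretical monoisotopic masses, adduct m/z values and isotopic
envelopes from molecular formulas, and matches observed features against a
local compound panel using a ppm mass threshold combined with an
isotopic-envelope similarity threshold (defaults: 5 ppm, 0.80 cosine).

Formula parsing and isotope masses/abundances come from pyteomics
(``mass.Composition`` and ``mass.nist_mass``); the aggregated-envelope
convolution and the matching logic live here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from pyteomics import mass as _pmass

from .errors import AdductError, FormulaError

log = logging.getLogger(__name__)

PROTON_MASS = 1.007276466879  # Da, H+ (H minus one electron)
ELECTRON_MASS = 0.000548579909  # Da

# label -> (mass delta added to the neutral monoisotopic mass, signed charge)
_ADDUCTS: dict[str, tuple[float, int]] = {}


def _register_adducts() -> None:
    na = _pmass.nist_mass["Na"][0][0]
    k = _pmass.nist_mass["K"][0][0]
    cl = _pmass.nist_mass["Cl"][0][0]
    nh4 = _pmass.calculate_mass(formula="NH4") - ELECTRON_MASS
    _ADDUCTS.update(
        {
            "[M+H]+": (PROTON_MASS, 1),
            "[M+2H]2+": (2 * PROTON_MASS, 2),
            "[M-H]-": (-PROTON_MASS, -1),
            "[M+Na]+": (na - ELECTRON_MASS, 1),
            "[M+K]+": (k - ELECTRON_MASS, 1),
            "[M+Cl]-": (cl + ELECTRON_MASS, -1),
            "[M+NH4]+": (nh4, 1),
        }
    )


_register_adducts()


def _normalize_adduct(label: str) -> str:
    return label.replace("−", "-").replace(" ", "")


def supported_adducts() -> list[str]:
    return sorted(_ADDUCTS)


def _composition(formula: str) -> dict[str, int]:
    if not formula or not formula.strip():
        raise FormulaError("empty molecular formula")
    try:
        comp = _pmass.Composition(formula=formula)
    except Exception as exc:  # pyteomics raises PyteomicsError
        raise FormulaError(f"cannot parse formula {formula!r}: {exc}") from exc
    if not comp:
        raise FormulaError(f"formula {formula!r} contains no atoms")
    for element, count in comp.items():
        if element not in _pmass.nist_mass:
            raise FormulaError(f"unknown element {element!r} in {formula!r}")
        if count <= 0:
            raise FormulaError(f"non-positive count for {element!r} in {formula!r}")
    return dict(comp)


def monoisotopic_mass(formula: str) -> float:
    """Monoisotopic (most-abundant-isotope) mass of a neutral formula, in Da."""
    comp = _composition(formula)
    return float(_pmass.calculate_mass(composition=_pmass.Composition(comp)))


def adduct_mz(neutral_mass: float, adduct: str, charge: int | None = None) -> float:
    """m/z of an adduct ion: (M + delta) / |z|, electron mass included.

    ``charge``, when given, must agree with the adduct label's charge.
    """
    label = _normalize_adduct(adduct)
    if label not in _ADDUCTS:
        raise AdductError(
            f"unsupported adduct {adduct!r}; supported: {supported_adducts()}"
        )
    delta, z = _ADDUCTS[label]
    if charge is not None and abs(charge) != abs(z):
        raise AdductError(f"charge {charge} inconsistent with adduct {adduct!r}")
    return (neutral_mass + delta) / abs(z)


def _element_isotope_table(element: str) -> tuple[np.ndarray, np.ndarray]:
    """(masses, abundances) over neutron-shift index 0..K for one element."""
    entries = [
        (m, ab)
        for iso, (m, ab) in _pmass.nist_mass[element].items()
        if iso != 0 and ab > 0.0
    ]
    entries.sort()
    base = round(entries[0][0])
    size = round(entries[-1][0]) - base + 1
    masses = np.zeros(size)
    abund = np.zeros(size)
    for m, ab in entries:
        k = round(m) - base
        masses[k] = m
        abund[k] = ab
    return masses, abund


def _convolve(a1, m1, a2, m2):
    """Convolve two (abundance, mean-mass) aggregated distributions."""
    n = len(a1) + len(a2) - 1
    a = np.zeros(n)
    wm = np.zeros(n)
    for i in range(len(a1)):
        if a1[i] == 0.0:
            continue
        for j in range(len(a2)):
            p = a1[i] * a2[j]
            if p == 0.0:
                continue
            a[i + j] += p
            wm[i + j] += p * (m1[i] + m2[j])
    m = np.divide(wm, a, out=np.zeros_like(wm), where=a > 0)
    return a, m


def theoretical_envelope(
    formula: str, adduct: str | None = None, n_isotopologues: int = 3
) -> list[tuple[float, float]]:
    """First ``n_isotopologues`` aggregated isotopologue peaks of a formula.

    Isotopologues are aggregated by neutron count (M, M+1, M+2, ...); each
    peak carries its abundance-weighted mean mass. Abundances are normalized
    so the largest peak is 1. With ``adduct`` given, peak positions are
    reported as m/z = (mass + adduct delta) / |z|; the isotope contribution
    of the adduct atoms themselves is neglected (sub-0.1% on abundances).
    """
    if n_isotopologues < 2:
        raise ValueError("n_isotopologues must be >= 2")
    comp = _composition(formula)
    acc_a = np.array([1.0])
    acc_m = np.array([0.0])
    for element, count in comp.items():
        e_m, e_a = _element_isotope_table(element)
        # binary exponentiation over the per-atom distribution
        base_a, base_m = e_a, e_m
        k = count
        while k:
            if k & 1:
                acc_a, acc_m = _convolve(acc_a, acc_m, base_a, base_m)
                acc_a, acc_m = acc_a[: n_isotopologues + 4], acc_m[: n_isotopologues + 4]
            k >>= 1
            if k:
                base_a, base_m = _convolve(base_a, base_m, base_a, base_m)
                base_a, base_m = base_a[: n_isotopologues + 4], base_m[: n_isotopologues + 4]
    acc_a = acc_a[:n_isotopologues]
    acc_m = acc_m[:n_isotopologues]
    acc_a = acc_a / acc_a.max()
    if adduct is not None:
        label = _normalize_adduct(adduct)
        if label not in _ADDUCTS:
            raise AdductError(f"unsupported adduct {adduct!r}")
        delta, z = _ADDUCTS[label]
        acc_m = (acc_m + delta) / abs(z)
    return [(float(m), float(a)) for m, a in zip(acc_m, acc_a)]


def ppm_error(observed_mz: float, theoretical_mz: float) -> float:
    """Signed mass error of ``observed_mz`` against theory, in ppm."""
    return (observed_mz - theoretical_mz) / theoretical_mz * 1e6


def envelope_similarity(
    observed: list[tuple[float, float]],
    theoretical: list[tuple[float, float]],
    match_ppm: float = 10.0,
) -> float:
    """Cosine similarity of matched isotopologue abundance vectors, in [0, 1].

    Peaks are matched by position within ``match_ppm``; fewer than two matched
    positions yields 0 with a warning (the envelope carries no shape
    information in that case). The metric is invariant to global intensity
    scaling of the observed envelope.
    """
    obs_v, theo_v = [], []
    for t_mz, t_ab in theoretical:
        best = None
        for o_mz, o_ab in observed:
            if abs(o_mz - t_mz) <= t_mz * match_ppm * 1e-6:
                if best is None or abs(o_mz - t_mz) < abs(best[0] - t_mz):
                    best = (o_mz, o_ab)
        if best is not None:
            obs_v.append(best[1])
            theo_v.append(t_ab)
    if len(obs_v) < 2:
        warnings.warn(
            "fewer than 2 matched isotopologue positions; similarity set to 0",
            stacklevel=2,
        )
        return 0.0
    a = np.asarray(obs_v, dtype=float)
    b = np.asarray(theo_v, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.clip(a @ b / (na * nb), 0.0, 1.0))


@dataclass
class CompoundRecord:
    """A panel compound with per-adduct theoretical m/z and envelopes."""

    name: str
    formula: str
    adducts: list[str]
    theoretical_mz: dict[str, float] = field(default_factory=dict)
    envelope: dict[str, list[tuple[float, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.adducts = [_normalize_adduct(a) for a in self.adducts]
        neutral = monoisotopic_mass(self.formula)
        for a in self.adducts:
            self.theoretical_mz.setdefault(a, adduct_mz(neutral, a))
            self.envelope.setdefault(a, theoretical_envelope(self.formula, a))


@dataclass
class AnnotationHit:
    feature_mz: float
    compound: str
    adduct: str
    ppm_error: float
    envelope_similarity: float


def annotate_feature(
    feature_mz: float,
    observed_envelope: list[tuple[float, float]] | None,
    panel: list[CompoundRecord],
    max_ppm: float = 5.0,
    min_similarity: float = 0.8,
) -> list[AnnotationHit]:
    """Rank panel matches for one observed feature.

    Candidates within ``max_ppm`` of any adduct m/z are scored by envelope
    cosine similarity and kept when similarity >= ``min_similarity``; hits are
    ranked by (similarity desc, |ppm| asc). With ``observed_envelope`` None
    the similarity test is skipped (similarity reported as 1.0), which
    reduces matching to the mass threshold alone.
    """
    if not panel:
        raise ValueError("empty compound panel")
    hits: list[AnnotationHit] = []
    for rec in panel:
        for adduct in rec.adducts:
            theo = rec.theoretical_mz[adduct]
            err = ppm_error(feature_mz, theo)
            if abs(err) > max_ppm:
                continue
            if observed_envelope is None:
                sim = 1.0
            else:
                sim = envelope_similarity(observed_envelope, rec.envelope[adduct])
            if sim < min_similarity:
                continue
            hits.append(AnnotationHit(feature_mz, rec.name, adduct, err, sim))
    hits.sort(key=lambda h: (-h.envelope_similarity, abs(h.ppm_error)))
    return hits


def annotate_table(
    feature_mzs,
    panel: list[CompoundRecord],
    observed_envelopes=None,
    max_ppm: float = 5.0,
    min_similarity: float = 0.8,
) -> dict[float, list[AnnotationHit]]:
    """Annotate every feature m/z; returns only features with >= 1 hit."""
    out: dict[float, list[AnnotationHit]] = {}
    for i, mz in enumerate(feature_mzs):
        env = None if observed_envelopes is None else observed_envelopes[i]
        hits = annotate_feature(mz, env, panel, max_ppm, min_similarity)
        if hits:
            out[float(mz)] = hits
    return out
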