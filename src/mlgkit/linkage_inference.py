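"""Linkage calling from CID peak lists by comparative diagnostic-ion logic.

The workflow mirrors how linkage positions of a linear gluco-oligomer are
deduced from a high-energy CID spectrum of the permethylated sodiated
species: each candidate linkage vector predicts a pattern of strong, weak
and absent diagnostic ions (3,5A and V series, internal D ions, and the
relative intensity of D1 against the isobaric E1/G1 pair at the
nonreducing terminus); the observed spectrum is classified ion by ion and
the candidate maximizing weighted agreement is called.  Reference spectra
of the two homopolymers (all-1,4 and all-1,3) can be supplied to add
comparative weight, as absolute intensities are instrument-dependent.

All quantitative thresholds here (absent < 1 %, weak 1-10 %, strong >=
30 % of the base peak; the D1/E1 ratio cutoffs 2 and 0.5; the 2:1
presence-vs-intensity weights) are package conventions that
operationalize the qualitative strong/weak/absent vocabulary of the
underlying chemistry; they are centralized below and documented as such.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .cid_fragments import (
    Feasibility,
    FragmentIon,
    MassSpec,
    PeakList,
    Series,
    enumerate_fragments,
    fragment_mz,
)
from .glucan_core import GlucanChain, Linkage
from .methylation_profile import LinkageProfile, predict_pmaa


@dataclass(frozen=True)
class ClassifierThresholds:
    """Intensity bands translating relative intensity into categories."""

    absent_below: float = 0.01
    weak_max: float = 0.10
    strong_min: float = 0.30

    def __post_init__(self) -> None:
        if not 0 < self.absent_below <= self.weak_max < self.strong_min <= 1:
            raise ValueError("thresholds must satisfy 0 < absent < weak_max < strong_min <= 1")


ABSENT = "absent"
WEAK = "present_weak"
STRONG = "present_strong"

_FEAS_TO_OBS = {
    Feasibility.STRONG: STRONG,
    Feasibility.WEAK: WEAK,
    Feasibility.INFEASIBLE: ABSENT,
}


@dataclass(frozen=True)
class Observation:
    """Classified observation of one expected ion in a spectrum."""

    category: str
    intensity: float
    borderline: bool = False


def classify_peak(
    peaks: PeakList,
    ion_mz: float,
    tolerance: float = 0.5,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> Observation:
    """Strong / weak / absent call for the ion position in a peak list.

    Intensities between the weak band and the strong floor are reported as
    weak with a borderline flag rather than forced into either band.
    """
    inten = peaks.intensity_at(ion_mz, tolerance)
    if inten < thresholds.absent_below:
        return Observation(ABSENT, inten)
    if inten >= thresholds.strong_min:
        return Observation(STRONG, inten)
    return Observation(WEAK, inten, borderline=inten > thresholds.weak_max)


# ---------------------------------------------------------------------------
# Evidence accumulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvidenceItem:
    ion_label: str
    observation: str
    implied_linkage: Optional[Linkage]
    weight: float


@dataclass(frozen=True)
class BondEvidence:
    bond: int
    items: Tuple[EvidenceItem, ...]
    called_linkage: Linkage
    confidence: float


@dataclass(frozen=True)
class EvidenceTable:
    """Per-bond diagnostic evidence for the called chain."""

    chain: GlucanChain
    bonds: Tuple[BondEvidence, ...]
    score: float
    max_score: float
    ambiguous: bool
    co_optimal: Tuple[GlucanChain, ...]


@dataclass(frozen=True)
class InferenceResult:
    chain: GlucanChain
    table: EvidenceTable


_PRESENCE_WEIGHT = 2.0
_INTENSITY_WEIGHT = 1.0
_D1_RATIO_HIGH = 2.0
_D1_RATIO_LOW = 0.5


def _diagnostic_ions(dp: int, spec: MassSpec) -> List[Tuple[Series, int, int]]:
    """Candidate-independent diagnostic ions: (series, index, diagnosed bond)."""
    ions: List[Tuple[Series, int, int]] = []
    for i in range(2, dp + 1):
        ions.append((Series.A35, i, i - 1))
    for i in range(2, dp):
        ions.append((Series.V, i, dp - i))
    for i in range(2, dp):
        ions.append((Series.D, i, i - 1))
    return ions


def _expected_categories(chain: GlucanChain) -> Dict[Tuple[Series, int], str]:
    return {
        (f.series, f.index): _FEAS_TO_OBS[f.feasibility]
        for f in enumerate_fragments(chain)
    }


def _pair_score(expected: str, observed: str, weight: float) -> float:
    if expected == observed:
        return weight
    if {expected, observed} == {STRONG, WEAK}:
        return weight / 2.0
    return 0.0


def _implied_from_observation(series: Series, bond: int, obs: Observation) -> Optional[Linkage]:
    """What a single classified ion suggests about its diagnosed bond."""
    if series is Series.A35:
        return {STRONG: Linkage.L4, ABSENT: Linkage.L3}.get(obs.category)
    if series is Series.V:
        if obs.category == STRONG:
            return Linkage.L4
        if obs.category == WEAK:
            return Linkage.L3 if bond > 1 else None
        return Linkage.L3 if bond == 1 else None
    if series is Series.D:
        return {STRONG: Linkage.L4, WEAK: Linkage.L4, ABSENT: Linkage.L3}.get(obs.category)
    return None


def _d1_ratio_call(
    peaks: PeakList, dp: int, spec: MassSpec, tolerance: float
) -> Tuple[Optional[Linkage], float]:
    """D1 vs E1/G1 intensity-ratio test for the nonreducing-terminal bond."""
    ref = GlucanChain((Linkage.L4,) * (dp - 1))
    d1 = peaks.intensity_at(fragment_mz(ref, Series.D, 1, spec), tolerance)
    e1 = peaks.intensity_at(fragment_mz(ref, Series.E, 1, spec), tolerance)
    if d1 <= 0 and e1 <= 0:
        return None, 0.0
    ratio = d1 / e1 if e1 > 0 else float("inf")
    if ratio > _D1_RATIO_HIGH:
        return Linkage.L3, ratio
    if ratio < _D1_RATIO_LOW:
        return Linkage.L4, ratio
    return None, ratio


def infer_structure(
    peaks: PeakList,
    dp: int,
    references: Optional[Tuple[PeakList, PeakList]] = None,
    tolerance: float = 0.5,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
    spec: MassSpec = MassSpec(),
    profile: Optional[LinkageProfile] = None,
) -> InferenceResult:
    """Call every linkage of a DP ``dp`` chain from its CID peak list.

    Scores all 2**(dp-1) candidates by weighted agreement between their
    predicted diagnostic-ion pattern and the classified observations
    (presence/absence diagnostics weight 2, intensity-comparative
    diagnostics weight 1).  ``references`` optionally supplies the
    (all-1,4 homopolymer, all-1,3 homopolymer) reference spectra whose
    per-ion categories contribute comparative weight.  An exact score tie
    is returned as an explicit ambiguity, not an exception.  A supplied
    PMAA ``profile`` (integer counts) restricts candidates to structures
    consistent with it.
    """
    if not 3 <= dp <= 8:
        raise ValueError("inference is supported for DP 3-8")
    if len(peaks) == 0:
        raise ValueError("cannot infer a structure from an empty peak list")

    diagnostics = _diagnostic_ions(dp, spec)
    ref_chain = GlucanChain((Linkage.L4,) * (dp - 1))
    observations: Dict[Tuple[Series, int], Observation] = {}
    for series, index, _bond in diagnostics:
        mz = fragment_mz(ref_chain, series, index, spec)
        observations[(series, index)] = classify_peak(peaks, mz, tolerance, thresholds)

    ratio_link, _ratio = _d1_ratio_call(peaks, dp, spec, tolerance)

    ref_categories: Dict[Tuple[Series, int], Tuple[str, str]] = {}
    if references is not None:
        ref_cello, ref_lamin = references
        for series, index, _bond in diagnostics:
            mz = fragment_mz(ref_chain, series, index, spec)
            ref_categories[(series, index)] = (
                classify_peak(ref_cello, mz, tolerance, thresholds).category,
                classify_peak(ref_lamin, mz, tolerance, thresholds).category,
            )

    candidates = [
        GlucanChain(vec)
        for vec in itertools.product((Linkage.L3, Linkage.L4), repeat=dp - 1)
    ]
    if profile is not None:
        target = tuple(round(c) for c in profile.as_tuple())
        candidates = [
            c
            for c in candidates
            if tuple(round(v) for v in predict_pmaa(c).as_tuple()) == target
        ]
        if not candidates:
            raise ValueError("no candidate structure is consistent with the supplied PMAA profile")

    def score(chain: GlucanChain) -> float:
        expected_map = _expected_categories(chain)
        s = 0.0
        for series, index, bond in diagnostics:
            expected = expected_map[(series, index)]
            obs = observations[(series, index)]
            s += _pair_score(expected, obs.category, _PRESENCE_WEIGHT)
            if references is not None:
                cello_cat, lamin_cat = ref_categories[(series, index)]
                matches_cello = obs.category == cello_cat
                matches_lamin = obs.category == lamin_cat
                if matches_cello != matches_lamin:
                    implied = Linkage.L4 if matches_cello else Linkage.L3
                    if chain.bond(bond) == implied:
                        s += _INTENSITY_WEIGHT
        if ratio_link is not None and chain.bond(1) == ratio_link:
            s += _INTENSITY_WEIGHT
        return s

    scored = sorted(
        ((score(c), c) for c in candidates), key=lambda sc: (-sc[0], str(sc[1]))
    )
    best_score = scored[0][0]
    co_optimal = tuple(c for s, c in scored if abs(s - best_score) < 1e-9)
    called = co_optimal[0]
    ambiguous = len(co_optimal) > 1

    max_score = (
        len(diagnostics) * _PRESENCE_WEIGHT
        + (len(diagnostics) * _INTENSITY_WEIGHT if references is not None else 0.0)
        + _INTENSITY_WEIGHT
    )

    bonds: List[BondEvidence] = []
    for bond in range(1, dp):
        items: List[EvidenceItem] = []
        for series, index, dbond in diagnostics:
            if dbond != bond:
                continue
            obs = observations[(series, index)]
            implied = _implied_from_observation(series, bond, obs)
            label = f"{series.pretty}{index}"
            items.append(EvidenceItem(label, obs.category, implied, _PRESENCE_WEIGHT))
        if bond == 1 and ratio_link is not None:
            items.append(
                EvidenceItem("D1/E1 ratio", STRONG if ratio_link == Linkage.L3 else WEAK,
                             ratio_link, _INTENSITY_WEIGHT)
            )
        informative = [it for it in items if it.implied_linkage is not None]
        concordant = sum(
            it.weight for it in informative if it.implied_linkage == called.bond(bond)
        )
        total = sum(it.weight for it in informative)
        confidence = concordant / total if total > 0 else 0.0
        bonds.append(BondEvidence(bond, tuple(items), called.bond(bond), confidence))

    table = EvidenceTable(
        chain=called,
        bonds=tuple(bonds),
        score=best_score,
        max_score=max_score,
        ambiguous=ambiguous,
        co_optimal=co_optimal,
    )
    return InferenceResult(called, table)


def evidence_report(table: EvidenceTable) -> str:
    """Human-readable deduction trail, nonreducing end first."""
    lines = [f"Called structure: {table.chain}  (score {table.score:g}/{table.max_score:g})"]
    if table.ambiguous:
        co = ", ".join(str(c) for c in table.co_optimal)
        lines.append(f"AMBIGUOUS: co-optimal structures {co}")
    for be in table.bonds:
        link_name = "1,3" if be.called_linkage == Linkage.L3 else "1,4"
        if be.confidence == 0.0:
            lines.append(
                f"bond {be.bond} (residue {be.bond}->{be.bond + 1}): "
                f"called {link_name} -- ambiguous (no informative diagnostic)"
            )
            continue
        parts = []
        for it in be.items:
            implied = (
                "1,3" if it.implied_linkage == Linkage.L3
                else "1,4" if it.implied_linkage == Linkage.L4
                else "inconclusive"
            )
            parts.append(f"{it.ion_label} {it.observation.replace('present_', '')} -> {implied}")
        lines.append(
            f"bond {be.bond} (residue {be.bond}->{be.bond + 1}): called {link_name} "
            f"(confidence {be.confidence:.2f}); " + "; ".join(parts)
        )
    return "\n".join(lines)
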