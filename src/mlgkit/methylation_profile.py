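"""PMAA linkage profiles: prediction from structures and candidate ranking.

Methylation analysis reads out, per residue, which hydroxyls were
glycosylated.  For a linear 1,3/1,4-glucan reduced at its reducing end
before methylation, the partially methylated alditol acetates fall into
five classes: t-Glc (the nonreducing terminus), 3-Glc and 4-Glc (internal
residues, by the linkage they accept), and 3-Glcol / 4-Glcol (the reduced
reducing terminus, by the linkage it accepts).  The analysis counts
classes but is blind to their order along the chain, which is why several
sequences can share one profile and mass spectrometry is needed to order
the linkages.

Observed molar ratios (normalized to t-Glc = 1.00) deviate from integers
because of recovery and derivatization bias, so candidate ranking uses a
least-squares shape comparison and reports exact ties as ties.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence

from .glucan_core import GlucanChain, Linkage

PROFILE_COLUMNS = ("t-Glc", "3-Glc", "4-Glc", "3-Glcol", "4-Glcol")


@dataclass(frozen=True)
class LinkageProfile:
    """Counts (or t-Glc-normalized ratios) of PMAA classes.

    ``normalized`` distinguishes raw integer counts (summing to DP) from
    wet-lab style molar ratios expressed with t-Glc = 1.00.
    """

    t_glc: float
    glc3: float
    glc4: float
    glcol3: float
    glcol4: float
    normalized: bool = False

    def as_tuple(self) -> tuple:
        return (self.t_glc, self.glc3, self.glc4, self.glcol3, self.glcol4)

    def as_dict(self) -> Dict[str, float]:
        return dict(zip(PROFILE_COLUMNS, self.as_tuple()))

    @property
    def total(self) -> float:
        return sum(self.as_tuple())

    def normalize(self) -> "LinkageProfile":
        """Express the profile with t-Glc taken as 1.00."""
        if self.t_glc == 0:
            raise ValueError("cannot normalize a profile without a t-Glc component")
        t = self.t_glc
        return LinkageProfile(
            1.0, self.glc3 / t, self.glc4 / t, self.glcol3 / t, self.glcol4 / t, True
        )


def predict_pmaa(chain: GlucanChain) -> LinkageProfile:
    """Integer PMAA profile of a reduced, methylated linear chain.

    Residue 1 gives t-Glc; internal residue i gives 3-Glc or 4-Glc by the
    linkage it accepts (bond i-1); the reducing residue gives 3-Glcol or
    4-Glcol the same way.  DP 1 is rejected: free glucitol has no class in
    this vocabulary.
    """
    if chain.dp < 2:
        raise ValueError("PMAA profile is defined for DP >= 2 (free glucitol has no class)")
    glc3 = sum(1 for l in chain.linkages[:-1] if l == Linkage.L3)
    glc4 = sum(1 for l in chain.linkages[:-1] if l == Linkage.L4)
    last = chain.linkages[-1]
    return LinkageProfile(
        t_glc=1,
        glc3=glc3,
        glc4=glc4,
        glcol3=1 if last == Linkage.L3 else 0,
        glcol4=1 if last == Linkage.L4 else 0,
    )


def candidate_structures(dp: int, profile: LinkageProfile) -> List[GlucanChain]:
    """All linear chains of the given DP whose PMAA profile matches.

    Exhaustive enumeration over the 2**(dp-1) linkage vectors, returned in
    lexicographic order (1,3 before 1,4).  The profile must be an integer
    profile consistent with the DP.
    """
    if not 2 <= dp <= 12:
        raise ValueError("candidate enumeration is bounded to 2 <= dp <= 12")
    counts = profile.as_tuple()
    if any(abs(c - round(c)) > 1e-9 for c in counts):
        raise ValueError("candidate_structures requires an integer (raw-count) profile")
    if round(profile.total) != dp:
        raise ValueError(
            f"profile classes sum to {profile.total:g}, inconsistent with DP {dp}"
        )
    target = tuple(round(c) for c in counts)
    out = []
    for vec in itertools.product((Linkage.L3, Linkage.L4), repeat=dp - 1):
        chain = GlucanChain(vec)
        pred = predict_pmaa(chain)
        if tuple(round(c) for c in pred.as_tuple()) == target:
            out.append(chain)
    return out


def profile_distance(observed: LinkageProfile, chain: GlucanChain) -> float:
    """Sum of squared deviations between observed ratios and a structure.

    The observed profile must be normalized to t-Glc = 1.00; the chain's
    integer profile is normalized the same way (t-Glc is 1 for any linear
    chain, so its integer counts are already on that scale).  Zero iff the
    observation matches the prediction exactly.
    """
    if not observed.normalized:
        observed = observed.normalize()
    pred = predict_pmaa(chain).normalize()
    return sum((o - p) ** 2 for o, p in zip(observed.as_tuple(), pred.as_tuple()))


def rank_candidates(
    observed: LinkageProfile, candidates: Sequence[GlucanChain]
) -> List[tuple]:
    """Rank candidate structures by profile distance; ties share a rank.

    Returns (chain, distance, rank) sorted by distance then notation; equal
    distances receive equal rank, making ties explicit rather than imposing
    an arbitrary order.
    """
    scored = sorted(
        ((c, profile_distance(observed, c)) for c in candidates),
        key=lambda cd: (cd[1], str(cd[0])),
    )
    ranked = []
    rank = 0
    prev = None
    for i, (chain, dist) in enumerate(scored):
        if prev is None or abs(dist - prev) > 1e-12:
            rank = i + 1
        ranked.append((chain, dist, rank))
        prev = dist
    return ranked


# ---------------------------------------------------------------------------
# TSV interchange mirroring the classical linkage-analysis table layout
# ---------------------------------------------------------------------------

def profiles_to_frame(profiles: Dict[str, LinkageProfile]):
    import pandas as pd

    return pd.DataFrame(
        [{"sample": name, **p.as_dict()} for name, p in profiles.items()],
        columns=["sample", *PROFILE_COLUMNS],
    )


def write_profiles(path: str | Path, profiles: Dict[str, LinkageProfile]) -> None:
    profiles_to_frame(profiles).to_csv(path, sep="\t", index=False)


def read_profiles(path: str | Path) -> Dict[str, LinkageProfile]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    out: Dict[str, LinkageProfile] = {}
    for _, row in df.iterrows():
        vals = [float(row[c]) for c in PROFILE_COLUMNS]
        out[str(row["sample"])] = LinkageProfile(*vals, normalized=vals[0] == 1.0)
    return out
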