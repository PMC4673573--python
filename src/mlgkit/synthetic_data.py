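"""Seeded generators for glucan chain populations and CID peak lists.

The chain generator works at the level of cellooligosaccharide units --
runs of 1,4-linked glucoses delimited by single 1,3 bonds -- because that
is the vocabulary in which grass mixed-linkage glucan fine structure is
described: mostly cellotriosyl and cellotetraosyl units, a rare
cellobiosyl unit (frequency below 2 % of units), and optionally long
1,4-stretches.  By default every cellobiosyl unit is immediately followed
on its reducing side by a cellotriosyl unit, reflecting where the
cellobiosyl motif sits in barley glucan; a free mode without that
adjacency exists for exploring other unit contexts.

The spectrum simulator turns the linkage-dependent feasibility categories
of the fragment calculator into peak lists: strong-feasible ions draw
intensities from a high band, weak-feasible ions from a low band,
infeasible ions are omitted; m/z values receive Gaussian jitter and a few
uniform noise peaks are added.  It emulates the qualitative
strong/weak/absent pattern of high-energy CID spectra, not detector
physics.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .cid_fragments import (
    Feasibility,
    MassSpec,
    PeakList,
    enumerate_fragments,
    precursor_mz,
    write_peaklist_tsv,
)
from .glucan_core import GlucanChain

CELLOPENTAOSE = "G4G4G4G4G"
LAMINARIPENTAOSE = "G3G3G3G3G"

# Pinned seeds for the shipped reference fixtures.
_FIXTURE_SEEDS = {"cellopentaose": 41, "laminaripentaose": 17}


class MLGParams(BaseModel):
    """Unit-composition parameters of a synthetic mixed-linkage glucan.

    ``p_cellobiosyl`` is the probability that a unit draw is a cellobiosyl
    unit (with forcing on, the draw emits the cellobiosyl-cellotriosyl
    pair, so the realized unit count slightly exceeds the draw count);
    the triosyl:tetraosyl ratio is renormalized over non-cellobiosyl
    draws.  ``long_stretch`` optionally adds rare all-1,4 stretches as
    (probability, (min_dp, max_dp)).  ``units_per_chain`` is the number of
    unit draws per chain; a fixed count or an inclusive (low, high) range.
    """

    model_config = ConfigDict(frozen=True)

    p_cellobiosyl: float = 0.01
    triosyl_tetraosyl_ratio: Tuple[float, float] = (0.697, 0.303)
    force_triosyl_after_cellobiosyl: bool = True
    long_stretch: Optional[Tuple[float, Tuple[int, int]]] = None
    units_per_chain: int | Tuple[int, int] = 4000
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "MLGParams":
        if not 0.0 <= self.p_cellobiosyl <= 1.0:
            raise ValueError("p_cellobiosyl must be in [0, 1]")
        a, b = self.triosyl_tetraosyl_ratio
        if a < 0 or b < 0 or a + b <= 0:
            raise ValueError("triosyl/tetraosyl weights must be nonnegative and not both zero")
        upc = self.units_per_chain
        low = upc if isinstance(upc, int) else upc[0]
        if low < 1:
            raise ValueError("units_per_chain must be >= 1")
        if (
            self.force_triosyl_after_cellobiosyl
            and self.p_cellobiosyl >= 1.0
            and low < 2
        ):
            raise ValueError(
                "every draw is a forced cellobiosyl-cellotriosyl pair; "
                "a one-unit chain is impossible"
            )
        if self.long_stretch is not None:
            p, (lo, hi) = self.long_stretch
            if not 0 <= p <= 1 or lo < 5 or hi < lo:
                raise ValueError("long_stretch must be (p in [0,1], (min_dp >= 5, max_dp >= min_dp))")
            if p + self.p_cellobiosyl > 1:
                raise ValueError("p_cellobiosyl + long-stretch probability exceeds 1")
        return self


def _chain_from_unit_lengths(lengths: np.ndarray) -> GlucanChain:
    """Concatenate units: 1,4 bonds inside units, 1,3 bonds between them."""
    total = int(lengths.sum())
    lk = np.full(total - 1, 4, dtype=np.uint8) if total > 1 else np.empty(0, dtype=np.uint8)
    cum = np.cumsum(lengths)[:-1]
    lk[cum - 1] = 3
    return GlucanChain(tuple(lk.tolist()))


def generate_mlg(params: MLGParams, n_chains: int) -> List[GlucanChain]:
    """Generate a seeded population of mixed-linkage glucan chains."""
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    rng = np.random.default_rng(params.seed)
    tri_w, tetra_w = params.triosyl_tetraosyl_ratio
    p_tri = tri_w / (tri_w + tetra_w)
    p_ls = params.long_stretch[0] if params.long_stretch else 0.0

    chains: List[GlucanChain] = []
    for _ in range(n_chains):
        upc = params.units_per_chain
        n_draws = (
            upc if isinstance(upc, int) else int(rng.integers(upc[0], upc[1] + 1))
        )
        r = rng.random(n_draws)
        cello = r < params.p_cellobiosyl
        stretch = (~cello) & (r < params.p_cellobiosyl + p_ls)
        tri = (~cello) & (~stretch) & (rng.random(n_draws) < p_tri)
        lengths = np.where(cello, 2, np.where(tri, 3, 4)).astype(np.int64)
        if params.long_stretch and stretch.any():
            lo, hi = params.long_stretch[1]
            lengths[stretch] = rng.integers(lo, hi + 1, size=int(stretch.sum()))
        if params.force_triosyl_after_cellobiosyl and cello.any():
            # expand each cellobiosyl draw into the (2, 3) unit pair
            before = np.cumsum(cello) - cello
            pos = np.arange(n_draws) + before
            out = np.empty(n_draws + int(cello.sum()), dtype=np.int64)
            out[pos] = lengths
            out[pos[cello] + 1] = 3
            lengths = out
        chains.append(_chain_from_unit_lengths(lengths))
    return chains


def unit_lengths_of(chain: GlucanChain) -> List[int]:
    """Decompose a chain back into cellooligosaccharide unit lengths."""
    lengths: List[int] = []
    run = 1
    for l in chain.linkages:
        if int(l) == 4:
            run += 1
        else:
            lengths.append(run)
            run = 1
    lengths.append(run)
    return lengths


class SpectrumSimConfig(BaseModel):
    """Intensity bands, jitter and noise model of the spectrum simulator."""

    model_config = ConfigDict(frozen=True)

    strong_band: Tuple[float, float] = (0.5, 1.0)
    weak_band: Tuple[float, float] = (0.02, 0.08)
    mz_sigma: float = 0.1
    n_noise_peaks: int = 10
    noise_max_intensity: float = 0.05
    scan_min_mz: float = 150.0
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SpectrumSimConfig":
        ws, we = self.weak_band
        ss, se = self.strong_band
        if not 0 < ws <= we <= ss <= se <= 1:
            raise ValueError("bands must be ordered 0 < weak <= strong <= 1")
        if self.mz_sigma < 0 or self.n_noise_peaks < 0 or self.noise_max_intensity < 0:
            raise ValueError("jitter and noise parameters must be nonnegative")
        return self


CLEAN_SIM = SpectrumSimConfig(mz_sigma=0.0, n_noise_peaks=0, seed=0)


def simulate_spectrum(
    chain: GlucanChain,
    config: SpectrumSimConfig,
    spec: MassSpec = MassSpec(),
) -> PeakList:
    """Simulated high-energy CID peak list of the permethylated chain.

    Strong-feasible ions draw from the strong band, weak-feasible from the
    weak band, infeasible ions are omitted; isobaric ions (the E1/G1 pair)
    collapse to the more intense draw.  Reproducible under a fixed seed.
    """
    if not 2 <= chain.dp <= 8:
        raise ValueError("spectrum simulation is supported for DP 2-8")
    rng = np.random.default_rng(config.seed)
    fragments = sorted(
        enumerate_fragments(chain, spec), key=lambda f: (f.series.value, f.index)
    )
    by_mz: dict = {}
    for frag in fragments:
        if frag.feasibility is Feasibility.INFEASIBLE:
            continue
        lo, hi = (
            config.strong_band
            if frag.feasibility is Feasibility.STRONG
            else config.weak_band
        )
        inten = float(rng.uniform(lo, hi))
        mz = frag.mz + float(rng.normal(0.0, config.mz_sigma)) if config.mz_sigma else frag.mz
        key = round(frag.mz, 6)  # merge exact isobars deterministically
        if key not in by_mz or inten > by_mz[key][1]:
            by_mz[key] = (mz, inten)
    pairs = list(by_mz.values())
    prec = precursor_mz(chain, spec)
    for _ in range(config.n_noise_peaks):
        mz = float(rng.uniform(config.scan_min_mz, prec + 10.0))
        inten = float(rng.uniform(0.0, config.noise_max_intensity))
        pairs.append((mz, inten))
    return PeakList.from_pairs(
        pairs,
        precursor_mz=prec,
        metadata={"chain": str(chain), "seed": str(config.seed)},
    )


def make_reference_fixtures(
    config: Optional[SpectrumSimConfig] = None,
) -> Tuple[PeakList, PeakList]:
    """Simulated cellopentaose and laminaripentaose reference spectra.

    With no config the pinned fixture seeds are used, so the return values
    regenerate the shipped fixture files exactly.  Both fixtures are
    synthetic stand-ins for instrument reference spectra.
    """
    from .glucan_core import parse_chain

    out = []
    for name, notation in (
        ("cellopentaose", CELLOPENTAOSE),
        ("laminaripentaose", LAMINARIPENTAOSE),
    ):
        cfg = config or SpectrumSimConfig(seed=_FIXTURE_SEEDS[name])
        pl = simulate_spectrum(parse_chain(notation), cfg)
        meta = dict(pl.metadata)
        meta["label"] = f"{name}_synthetic"
        out.append(PeakList(pl.peaks, pl.precursor_mz, meta))
    return out[0], out[1]


def fixture_path(name: str) -> Path:
    """Path of a packaged synthetic reference fixture TSV."""
    res = resources.files("mlgkit").joinpath(f"data/spectra/{name}_synthetic.tsv")
    with resources.as_file(res) as p:
        return Path(p)


def load_reference_fixtures() -> Tuple[PeakList, PeakList]:
    from .cid_fragments import read_peaklist_tsv

    return (
        read_peaklist_tsv(fixture_path("cellopentaose")),
        read_peaklist_tsv(fixture_path("laminaripentaose")),
    )


def write_fixture_files(directory: Path) -> List[Path]:
    """Regenerate the packaged fixture TSVs plus a checksum manifest."""
    directory.mkdir(parents=True, exist_ok=True)
    cello, lamin = make_reference_fixtures()
    paths = []
    for name, pl in (("cellopentaose", cello), ("laminaripentaose", lamin)):
        path = directory / f"{name}_synthetic.tsv"
        write_peaklist_tsv(path, pl)
        paths.append(path)
    manifest = directory.parent / "CHECKSUMS.sha256"
    with open(manifest, "w") as fh:
        for path in paths:
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            fh.write(f"{digest}  spectra/{path.name}\n")
    paths.append(manifest)
    return paths
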