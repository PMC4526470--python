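"""Synthetic Cq-data generator with known ground truth.

Emulates a single two-condition RT-qPCR reference-gene experiment: each
gene has a base Cq (its expression level), an optional condition shift
(cycles added in the stressed group — a truly stable reference has shift
0), biological noise, and technical (well-to-well) noise; each sample
additionally carries a shared RNA-loading offset that moves every gene in
that sample together.  All effects are Gaussian on the Cq scale, i.e.
log-normal and multiplicative on transcript abundance.

The generative model for gene g, biological sample s, well t is::

    Cq[g,s,t] = base_cq[g] + shift[g]*1[s stressed] + loading[s]
                + b[g,s] + e[g,s,t]

with loading ~ N(0, loading_sd), b ~ N(0, noise_sd[g]),
e ~ N(0, tech_sd[g]).  Ground-truth stability orders genes by the
lexicographic key (|shift|, noise_sd): condition bias first, scatter
second.

:func:`soybean_preset` reproduces the structure of a ten-candidate soybean
biotic-stress screen — base Cq 17.5-28 cycles, two engineered co-stable
genes, one engineered clearly-unstable gene (condition shift plus the
largest scatter, raw-Cq SD around one cycle), control vs stressed with
three biological replicates each, duplicate wells.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ct_data import CtTable

__all__ = [
    "GeneSpec",
    "SyntheticSpec",
    "GroundTruth",
    "simulate_ct",
    "soybean_preset",
    "paper_like_preset",
    "load_spec",
    "save_spec",
]


@dataclass(frozen=True)
class GeneSpec:
    """Generative parameters of one candidate gene (all in Cq cycles)."""

    name: str
    base_cq: float
    condition_shift: float = 0.0
    noise_sd: float = 0.2
    tech_sd: float = 0.1


@dataclass(frozen=True)
class SyntheticSpec:
    """Full generative specification of a synthetic experiment."""

    genes: tuple[GeneSpec, ...]
    n_bio_per_group: int = 3
    n_tech: int = 2
    loading_sd: float = 0.3
    seed: int = 1
    groups: tuple[str, str] = ("control", "stressed")

    def __post_init__(self) -> None:
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene names in synthetic spec")
        if len(self.genes) < 2:
            raise ValueError("need >=2 genes")
        if self.n_bio_per_group < 2:
            raise ValueError("need >=2 biological replicates per group")
        if self.n_tech < 1:
            raise ValueError("need >=1 technical replicate")
        if self.loading_sd < 0:
            raise ValueError("loading_sd must be >= 0")
        for g in self.genes:
            if not (10.0 < g.base_cq < 35.0):
                raise ValueError(f"{g.name}: base_cq {g.base_cq} outside (10, 35)")
            if g.noise_sd < 0 or g.tech_sd < 0:
                raise ValueError(f"{g.name}: negative noise SD")

    def with_seed(self, seed: int) -> "SyntheticSpec":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """What the generator actually injected, for recovery tests."""

    spec: SyntheticSpec
    stability_order: list[str]  # most -> least stable by (|shift|, noise_sd)
    loading: pd.Series
    bio_effects: pd.DataFrame  # genes x samples

    @property
    def least_stable(self) -> str:
        return self.stability_order[-1]

    @property
    def most_stable_pair(self) -> tuple[str, str]:
        return (self.stability_order[0], self.stability_order[1])


def simulate_ct(spec: SyntheticSpec) -> tuple[CtTable, GroundTruth]:
    """Draw one synthetic Cq table (deterministic for a fixed seed)."""
    rng = np.random.default_rng(spec.seed)
    control, stressed = spec.groups
    samples = [
        f"{grp}_{r + 1}"
        for grp in (control, stressed)
        for r in range(spec.n_bio_per_group)
    ]
    is_stressed = np.array([s.startswith(stressed) for s in samples])
    n_s = len(samples)
    g = len(spec.genes)

    loading = rng.normal(0.0, spec.loading_sd, size=n_s) if spec.loading_sd else np.zeros(n_s)
    noise_sd = np.array([gs.noise_sd for gs in spec.genes])
    tech_sd = np.array([gs.tech_sd for gs in spec.genes])
    base = np.array([gs.base_cq for gs in spec.genes])
    shift = np.array([gs.condition_shift for gs in spec.genes])

    bio = rng.normal(0.0, 1.0, size=(g, n_s)) * noise_sd[:, None]
    tech = rng.normal(0.0, 1.0, size=(g, n_s, spec.n_tech)) * tech_sd[:, None, None]
    cq = (
        base[:, None, None]
        + (shift[:, None] * is_stressed[None, :])[:, :, None]
        + loading[None, :, None]
        + bio[:, :, None]
        + tech
    )

    names = [gs.name for gs in spec.genes]
    if spec.n_tech == 1:
        frame = pd.DataFrame(cq[:, :, 0], index=names, columns=samples)
    else:
        cols = pd.MultiIndex.from_tuples(
            [(s, t + 1) for s in samples for t in range(spec.n_tech)],
            names=["sample", "tech_rep"],
        )
        frame = pd.DataFrame(cq.reshape(g, -1), index=names, columns=cols)
    design = pd.DataFrame(
        {
            "group": [control if not st else stressed for st in is_stressed],
            "bio_rep": [int(s.split("_")[-1]) for s in samples],
        },
        index=pd.Index(samples, name="sample"),
    )
    table = CtTable(frame, design)

    order = sorted(
        range(g), key=lambda i: (abs(shift[i]), noise_sd[i], i)
    )
    truth = GroundTruth(
        spec=spec,
        stability_order=[names[i] for i in order],
        loading=pd.Series(loading, index=samples, name="loading"),
        bio_effects=pd.DataFrame(bio, index=names, columns=samples),
    )
    return table, truth


#: Ten-candidate soybean-style preset.  Base Cq follow the observed
#: expression levels of the usual soybean candidates (CYP/EF1A high,
#: UNK2 low).  ABCT and FBOX are the engineered co-stable pair; GPDH is
#: the engineered unstable gene, with a 1.5-cycle condition shift plus the
#: largest biological scatter so its raw-Cq SD lands near one cycle — the
#: dispersion an unstable candidate shows in real biotic-stress screens.
PRESET_GENES: tuple[GeneSpec, ...] = (
    GeneSpec("ABCT", 22.0, condition_shift=0.0, noise_sd=0.15),
    GeneSpec("CYP", 17.5, condition_shift=0.0, noise_sd=0.35),
    GeneSpec("EF1A", 19.0, condition_shift=0.2, noise_sd=0.40),
    GeneSpec("FBOX", 23.0, condition_shift=0.0, noise_sd=0.15),
    GeneSpec("GPDH", 21.0, condition_shift=2.0, noise_sd=0.50),
    GeneSpec("RPL30", 24.0, condition_shift=0.5, noise_sd=0.50),
    GeneSpec("TUA4", 20.0, condition_shift=0.0, noise_sd=0.35),
    GeneSpec("TUB4", 21.5, condition_shift=0.2, noise_sd=0.40),
    GeneSpec("TUA5", 22.5, condition_shift=0.3, noise_sd=0.45),
    GeneSpec("UNK2", 28.0, condition_shift=0.4, noise_sd=0.45),
)


def soybean_preset(seed: int = 1) -> SyntheticSpec:
    """The fixed ten-gene soybean-style preset (3 bio x 2 tech, 2 groups)."""
    return SyntheticSpec(
        genes=PRESET_GENES,
        n_bio_per_group=3,
        n_tech=2,
        loading_sd=0.3,
        seed=seed,
    )


#: Alias kept for discoverability from the docs.
paper_like_preset = soybean_preset


def save_spec(spec: SyntheticSpec, path: str | Path) -> None:
    """Write a generative spec as YAML (round-trips with :func:`load_spec`)."""
    payload = asdict(spec)
    payload["genes"] = [asdict(g) for g in spec.genes]
    payload["groups"] = list(spec.groups)
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_spec(path: str | Path) -> SyntheticSpec:
    """Read a custom scenario spec from YAML."""
    payload = yaml.safe_load(Path(path).read_text())
    genes = tuple(GeneSpec(**g) for g in payload.pop("genes"))
    groups = tuple(payload.pop("groups", ("control", "stressed")))
    return SyntheticSpec(genes=genes, groups=groups, **payload)
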