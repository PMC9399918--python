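"""Synthetic cohort generator with planted stage-wise directed coupling.

The study's rat recordings are available only on request, so validation
runs on a synthetic cohort that emulates their statistical structure: K
animals split into a MYO group (recordings end at the myoclonic stage) and
a GTCS group (recordings include the tonic-clonic stage), three channels
(TH, HP, CX) at 1 kHz, and stage durations of unequal length with jitter.

Within each stage the channels evolve as a first-order vector
autoregression x_t = A_s x_{t-1} + e_t with Gaussian innovations; a nonzero
off-diagonal entry a_ij plants a directed influence channel_j -> channel_i
and defines the intra-slice ground-truth arc set.  Cross-stage dependence
is planted by *carry-over*: a weighted, linearly resampled copy of an
earlier stage's channel is mixed into a later stage's channel, which is
exactly the kind of row-aligned dependence the variable-table analysis can
detect.  This is an emulation target for the pipeline, not a biophysical
model of local field potentials.

Coupling weights are calibrated so that every planted arc carries a
comparable, strong contemporaneous correlation (|r| ~ 0.6-0.8) in every
stage: the preictal TH<->CX loop reverberates and amplifies shared variance
on its own, while the acyclic GTCS chain needs a higher autocorrelation and
coupling weight to plant dependence of the same strength.

Default conditions mirror the study: 21 animals of which 11 reach GTCS,
stage durations basal 120 s, infusion 300 s, MYO 60 s, GTCS 40 s (+/-20 %
jitter) at 1 kHz, and the consensus connectivity pattern planted
as coupling: TH->HP plus a bidirectional TH<->CX loop during basal /
infusion / MYO, and CX->TH with TH->HP during GTCS; carry-over links each
stage to the next through the CX channel, with no direct basal->GTCS term.
A ``scale`` factor shrinks all durations for fast experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .preprocess import (CHANNELS, SLICES, Group, Recording, StageAnnotation,
                         write_annotation)

#: index of each channel in the coupling matrices
_CH_INDEX = {ch: i for i, ch in enumerate(CHANNELS)}


def _preictal_coupling(diag: float = 0.65, c: float = 0.3) -> np.ndarray:
    """Basal/infusion/MYO pattern: TH -> HP, TH <-> CX."""
    a = np.eye(3) * diag
    a[_CH_INDEX["HP"], _CH_INDEX["TH"]] = c  # TH -> HP
    a[_CH_INDEX["CX"], _CH_INDEX["TH"]] = c  # TH -> CX
    a[_CH_INDEX["TH"], _CH_INDEX["CX"]] = c  # CX -> TH
    return a


def _gtcs_coupling(diag: float = 0.85, c: float = 0.5) -> np.ndarray:
    """GTCS pattern: CX -> TH, TH -> HP."""
    a = np.eye(3) * diag
    a[_CH_INDEX["TH"], _CH_INDEX["CX"]] = c  # CX -> TH
    a[_CH_INDEX["HP"], _CH_INDEX["TH"]] = c  # TH -> HP
    return a


def _default_coupling() -> dict[str, np.ndarray]:
    return {"basal": _preictal_coupling(),
            "infusion": _preictal_coupling(),
            "myo": _preictal_coupling(),
            "gtcs": _gtcs_coupling()}


def _default_carryover() -> dict[tuple[str, str], list[tuple[str, str, float]]]:
    # chain basal -> infusion -> myo -> gtcs through CX; no basal -> gtcs term.
    # CX is the one channel that is never the lone driver of a
    # direction-critical planted arc (it sits in the direction-free TH<->CX
    # loop preictally and is the source of the GTCS chain), so cross-stage
    # mixing into CX plants detectable inter-stage dependence without
    # distorting or de-identifying the planted intra-stage orientations.
    return {("basal", "infusion"): [("CX", "CX", 0.6)],
            ("infusion", "myo"): [("CX", "CX", 0.6)],
            ("myo", "gtcs"): [("CX", "CX", 0.6)]}


def _default_durations() -> dict[str, tuple[float, float]]:
    # (mean seconds, jitter fraction)
    return {"basal": (120.0, 0.2), "infusion": (300.0, 0.2),
            "myo": (60.0, 0.2), "gtcs": (40.0, 0.2)}


@dataclass
class SynthCohortConfig:
    n_animals: int = 21
    gtcs_fraction: float = 11 / 21
    sample_rate: float = 1000.0
    channels: tuple[str, ...] = CHANNELS
    slice_durations: dict[str, tuple[float, float]] = field(
        default_factory=_default_durations)
    coupling: dict[str, np.ndarray] = field(default_factory=_default_coupling)
    carryover: dict[tuple[str, str], list[tuple[str, str, float]]] = field(
        default_factory=_default_carryover)
    noise_sd: float = 1.0
    scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gtcs_fraction <= 1.0:
            raise ConfigError("gtcs_fraction must lie in [0, 1]")
        if self.n_animals < 1 or self.sample_rate <= 0 or self.scale <= 0:
            raise ConfigError("n_animals, sample_rate and scale must be positive")
        for sl, (mean, jitter) in self.slice_durations.items():
            if mean <= 0 or not 0.0 <= jitter < 1.0:
                raise ConfigError(f"bad duration spec for slice {sl!r}")
        for sl, a in self.coupling.items():
            a = np.asarray(a, dtype=float)
            if a.shape != (len(self.channels),) * 2:
                raise ConfigError(f"coupling matrix for {sl!r} has wrong shape")
            rho = float(np.max(np.abs(np.linalg.eigvals(a))))
            if rho >= 1.0:
                raise ConfigError(
                    f"coupling matrix for slice {sl!r} is unstable "
                    f"(spectral radius {rho:.3f} >= 1)")
            self.coupling[sl] = a

    def n_gtcs_animals(self) -> int:
        return round(self.n_animals * self.gtcs_fraction)


def study_preset(scale: float = 1.0, seed: int = 0,
                 **overrides) -> SynthCohortConfig:
    """The study-cohort preset: the defaults, plus a scale factor."""
    return SynthCohortConfig(scale=scale, seed=seed, **overrides)


@dataclass
class GroundTruth:
    """Planted (channel, slice)-level arcs implied by the configuration."""

    intra: set[tuple[str, str]]
    inter: set[tuple[str, str]]

    @property
    def all_arcs(self) -> set[tuple[str, str]]:
        return self.intra | self.inter


def ground_truth(cfg: SynthCohortConfig,
                 slices: tuple[str, ...] = SLICES) -> GroundTruth:
    """Ground truth over the given slices (3 slices for MYO-group animals)."""
    intra: set[tuple[str, str]] = set()
    for sl in slices:
        a = cfg.coupling[sl]
        for i, ch_i in enumerate(cfg.channels):
            for j, ch_j in enumerate(cfg.channels):
                if i != j and a[i, j] != 0.0:
                    intra.add((f"{ch_j}_{sl}", f"{ch_i}_{sl}"))
    inter: set[tuple[str, str]] = set()
    for (s_from, s_to), links in cfg.carryover.items():
        if s_from in slices and s_to in slices:
            for ch_from, ch_to, w in links:
                if w != 0.0:
                    inter.add((f"{ch_from}_{s_from}", f"{ch_to}_{s_to}"))
    return GroundTruth(intra=intra, inter=inter)


# ---------------------------------------------------------------------------
# simulation


def _simulate_var(a: np.ndarray, n: int, noise_sd: float,
                  rng: np.random.Generator, burn_in: int = 200) -> np.ndarray:
    """Stationary draw from x_t = A x_{t-1} + e_t, shape (channels, n)."""
    d = a.shape[0]
    eps = rng.normal(0.0, noise_sd, size=(d, burn_in + n))
    x = np.empty((d, burn_in + n))
    x[:, 0] = eps[:, 0]
    for t in range(1, burn_in + n):
        x[:, t] = a @ x[:, t - 1] + eps[:, t]
    return x[:, burn_in:]


def _resample_linear(x: np.ndarray, n: int) -> np.ndarray:
    if x.size == n:
        return x.copy()
    return np.interp(np.linspace(0.0, x.size - 1.0, n), np.arange(x.size), x)


def generate_animal(cfg: SynthCohortConfig, animal_index: int,
                    rng: np.random.Generator
                    ) -> tuple[Recording, StageAnnotation, GroundTruth]:
    """One animal: stage-wise VAR signals, carry-over mixing, annotation.

    Animals with ``animal_index < n_gtcs_animals()`` belong to the GTCS
    group; the rest stop after MYO.  GTCS recordings keep a short post-ictal
    refractory tail after the annotated end, which preprocessing discards.
    """
    is_gtcs = animal_index < cfg.n_gtcs_animals()
    group = Group.GTCS_GROUP if is_gtcs else Group.MYO_GROUP
    slices = SLICES if is_gtcs else SLICES[:-1]

    n_samples: dict[str, int] = {}
    for sl in slices:
        mean, jitter = cfg.slice_durations[sl]
        dur = mean * cfg.scale * (1.0 + rng.uniform(-jitter, jitter))
        n_samples[sl] = max(4, int(round(dur * cfg.sample_rate)))

    signals: dict[str, np.ndarray] = {}
    for sl in slices:
        x = _simulate_var(cfg.coupling[sl], n_samples[sl], cfg.noise_sd, rng)
        for (s_from, s_to), links in cfg.carryover.items():
            if s_to != sl or s_from not in signals:
                continue
            for ch_from, ch_to, w in links:
                if w == 0.0:
                    continue
                src = signals[s_from][_CH_INDEX[ch_from]]
                x[_CH_INDEX[ch_to]] += w * _resample_linear(src, n_samples[sl])
        signals[sl] = x

    parts = [signals[sl] for sl in slices]
    if is_gtcs:  # refractory tail beyond the annotated end
        n_tail = max(4, int(round(5.0 * cfg.scale * cfg.sample_rate)))
        parts.append(_simulate_var(cfg.coupling["gtcs"], n_tail,
                                   cfg.noise_sd, rng))
    samples = np.concatenate(parts, axis=1)

    starts, t = {}, 0
    for sl in slices:
        starts[sl] = t / cfg.sample_rate
        t += n_samples[sl]
    annotation = StageAnnotation(
        animal_id=f"animal_{animal_index:02d}",
        group=group,
        starts=starts,
        recording_end=t / cfg.sample_rate,
    )
    recording = Recording(animal_id=annotation.animal_id, group=group,
                          sample_rate=cfg.sample_rate,
                          channels=cfg.channels, samples=samples)
    return recording, annotation, ground_truth(cfg, slices)


def animal_rngs(cfg: SynthCohortConfig) -> list[np.random.Generator]:
    """One independent substream per animal, derived from the master seed."""
    seq = np.random.SeedSequence(cfg.seed)
    return [np.random.default_rng(child) for child in seq.spawn(cfg.n_animals)]


def generate_cohort_memory(cfg: SynthCohortConfig
                           ) -> list[tuple[Recording, StageAnnotation, GroundTruth]]:
    """The full cohort, in memory, fully reproducible from (cfg, seed)."""
    return [generate_animal(cfg, i, rng)
            for i, rng in enumerate(animal_rngs(cfg))]


def generate_cohort(cfg: SynthCohortConfig, out_dir: str | Path) -> dict:
    """Write one signal CSV + one annotation file per animal, the cohort
    manifest and the ground-truth arc lists; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "scale": cfg.scale,
                      "sample_rate": cfg.sample_rate, "animals": []}
    for rec, ann, _ in generate_cohort_memory(cfg):
        sig_path = out / f"{rec.animal_id}.csv"
        ann_path = out / f"{rec.animal_id}.annotation.json"
        frame = pd.DataFrame(rec.samples.T, columns=list(rec.channels))
        frame.to_csv(sig_path, index=False, float_format="%.6f")
        write_annotation(ann, ann_path, sample_rate=cfg.sample_rate)
        manifest["animals"].append({
            "animal_id": rec.animal_id,
            "group": rec.group.value,
            "signal": sig_path.name,
            "annotation": ann_path.name,
        })

    gt_full = ground_truth(cfg, SLICES)
    truth_frame = pd.DataFrame(
        sorted([(u, v, "intra") for u, v in gt_full.intra]
               + [(u, v, "inter") for u, v in gt_full.inter]),
        columns=["source", "target", "kind"])
    truth_frame.to_csv(out / "ground_truth.csv", index=False)

    import networkx as nx
    g = nx.DiGraph()
    g.add_edges_from(gt_full.all_arcs)
    nx.write_graphml(g, out / "ground_truth.graphml")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def scaled(cfg: SynthCohortConfig, scale: float) -> SynthCohortConfig:
    """Copy of the configuration with a different duration scale."""
    return replace(cfg, scale=scale)
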