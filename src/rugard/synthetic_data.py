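"""Synthetic palate cohorts and parameter libraries with known ground truth.

The stripe generator emulates the phenomenology of sequential ruga
formation: the palate grows linearly just anterior to ruga 8, new Shh
stripes appear at a fixed distance anterior to ruga 8 on a regular
schedule, and established stripes are carried anteriorly with the growing
tissue, so anteroposterior position doubles as a record of stripe age.
Each pathway reads out the stripe pattern either in phase with Shh or
inverted, switching on only once a stripe has existed for the gene's onset
lag — which is what the kymograph onset-correlation analysis is designed to
recover.  Staining noise, embryo weights and contralateral inhibitor
effects (width/intensity shifts, loss below a detection threshold) are
layered on top.

Everything is seeded; the ground-truth tables suffice to score the
quantification pipeline without inspecting generator internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rd_core import SignedTopology, sample_parameter_set
from .stability import classify_ddi
from .ruga_quant import ExpressionProfile

__all__ = [
    "SyntheticCohortSpec",
    "GENE_PHASES",
    "GENE_LAGS",
    "synth_parameter_library",
    "synth_profile_series",
    "synth_contralateral_pair",
]

#: pathway target readouts: phase relative to the Shh stripes and onset lag (days)
GENE_PHASES = {
    "Shh": +1,
    "Lef1": +1,        # Wnt target, epithelium: in phase, simultaneous
    "Pea3_epi": -1,    # FGF target, epithelium: out of phase, simultaneous
    "Gli1": +1,        # Hh target: in phase, lags
    "Id1": -1,         # BMP target: out of phase, lags
    "Pea3_mes": +1,    # FGF target, mesenchyme: in phase, lags
}
GENE_LAGS = {
    "Shh": 0.0,
    "Lef1": 0.0,
    "Pea3_epi": 0.0,
    "Gli1": 0.15,
    "Id1": 0.25,
    "Pea3_mes": 0.3,
}


@dataclass
class SyntheticCohortSpec:
    n_specimens: int = 60
    age_range: tuple = (12.5, 14.0)  # embryonic days
    wavelength: float = 150.0  # stripe spacing, um
    stripe_width: float = 60.0  # full width of a stripe bump, um
    stripe_interval: float = 0.4  # days between successive stripe onsets
    first_onset: float = 12.5  # onset time of the oldest (ruga 3) stripe
    n_prepattern: int = 2  # stripes already on schedule before first_onset
    n_anterior: int = 2  # established rugae anterior of the ruga-3 anchor (rugae 1-2)
    genes: tuple = ("Shh", "Lef1", "Pea3_epi", "Gli1", "Id1", "Pea3_mes")
    phases: dict = field(default_factory=lambda: dict(GENE_PHASES))
    lags: dict = field(default_factory=lambda: dict(GENE_LAGS))
    noise_additive: float = 0.03
    noise_multiplicative: float = 0.05
    sample_step: float = 10.0  # profile sampling, um
    weight_at_start: float = 50.0  # mg at the start of the age range
    weight_growth: float = 200.0  # mg per day
    weight_bin: float = 25.0
    seed: int = 0

    @property
    def growth_rate(self) -> float:
        """Tissue growth anterior to ruga 8 (um/day): one wavelength per
        stripe interval, so stripes appear evenly spaced."""
        return self.wavelength / self.stripe_interval

    def stripes(self, age: float):
        """(centres, onset times) of the stripes present at the given age,
        sorted by position (um anterior of ruga 8; ruga 8 itself at 0).

        Stripe ``j`` switches on at ``first_onset + (j - 1 - n_prepattern) *
        stripe_interval``, is born one wavelength anterior of ruga 8 and is
        then carried anteriorly by tissue growth, so older stripes lie more
        anterior.
        """
        pairs = [(0.0, self.first_onset - (self.n_prepattern + 1) * self.stripe_interval)]
        j = 1 - self.n_anterior
        while True:
            t_on = self.first_onset + (j - 1 - self.n_prepattern) * self.stripe_interval
            if t_on > age:
                break
            pairs.append((self.wavelength + self.growth_rate * (age - t_on), t_on))
            j += 1
        pairs.sort()
        pos = np.array([p for p, _ in pairs])
        ons = np.array([t for _, t in pairs])
        return pos, ons

    def stripe_positions(self, age: float) -> np.ndarray:
        return self.stripes(age)[0]

    def stripe_onsets(self, age: float) -> np.ndarray:
        return self.stripes(age)[1]


def _bump(x, centre, width):
    """Raised-cosine bump of unit height and given full width."""
    u = (x - centre) / (width / 2.0)
    out = np.zeros_like(x)
    m = np.abs(u) < 1
    out[m] = 0.5 * (1 + np.cos(np.pi * u[m]))
    return out


def _pattern(spec: SyntheticCohortSpec, x, age, gene):
    """Noise-free intensity for one gene at one age on axis x (um rel. ruga 8)."""
    centres = spec.stripe_positions(age)
    onsets = spec.stripe_onsets(age)
    lag = spec.lags[gene]
    ramp = np.clip((age - onsets - lag) / 0.05, 0.0, 1.0)  # sharp switch-on
    present = np.clip((age - onsets) / 0.05, 0.0, 1.0)  # stripe exists at all
    stripes = np.zeros_like(x)
    coverage = np.zeros_like(x)
    for c, r, pr in zip(centres, ramp, present):
        stripes += r * _bump(x, c, spec.stripe_width)
        coverage += pr * _bump(x, c, 2.0 * spec.wavelength)
    coverage = np.clip(coverage, 0.0, 1.0)
    stripes = np.clip(stripes, 0.0, 1.0)
    if spec.phases[gene] > 0:
        return stripes
    # out-of-phase readouts are expressed broadly and are *lost* at stripes
    # once the pathway engages (the loss carries the onset lag)
    return np.clip(coverage - stripes, 0.0, 1.0)


def _normalise(y):
    lo, hi = float(np.min(y)), float(np.max(y))
    if hi - lo < 1e-12:
        return np.zeros_like(y)
    return (y - lo) / (hi - lo)


def _specimen_profile(spec, rng, age, gene, specimen_id, effect=None):
    L = spec.stripe_positions(age).max() + 1.5 * spec.wavelength
    x = np.arange(-spec.wavelength, L, spec.sample_step)
    y = _pattern(spec, x, age, gene)
    truth_centres = spec.stripe_positions(age)
    if effect is not None:
        y = _apply_effect(spec, x, age, gene, effect)
    if spec.noise_multiplicative > 0:
        y = y * (1 + rng.normal(0, spec.noise_multiplicative, y.shape))
    if spec.noise_additive > 0:
        y = y + rng.normal(0, spec.noise_additive, y.shape)
    y = _normalise(np.clip(y, 0, 1))
    # anchors: ruga 8 at x=0; ruga 3 = the third-most-anterior stripe (rugae
    # 1 and 2 lie anterior of it)
    ruga3 = float(np.sort(truth_centres)[-(spec.n_anterior + 1)])
    weight = (
        spec.weight_at_start
        + spec.weight_growth * (age - spec.age_range[0])
        + rng.normal(0, spec.weight_bin / 4)
    )
    weight = np.round(weight / spec.weight_bin) * spec.weight_bin
    prof = ExpressionProfile(
        positions=x,
        intensity=y,
        gene=gene,
        specimen_id=specimen_id,
        ruga3=ruga3,
        ruga8=0.0,
        weight_mg=float(weight),
    )
    return prof


def _apply_effect(spec, x, age, gene, effect):
    """Contralateral inhibitor effect: per-stripe width/intensity scaling and
    loss below a detection threshold."""
    centres = spec.stripe_positions(age)
    onsets = spec.stripe_onsets(age)
    lag = spec.lags[gene]
    ramp = np.clip((age - onsets - lag) / 0.05, 0.0, 1.0)
    w = spec.stripe_width * (1.0 + effect.get("width_change", 0.0))
    amp = 1.0 + effect.get("intensity_change", 0.0)
    thr = effect.get("detection_threshold", 0.0)
    present = np.clip((age - onsets) / 0.05, 0.0, 1.0)
    stripes = np.zeros_like(x)
    coverage = np.zeros_like(x)
    for c, r, pr in zip(centres, ramp, present):
        height = np.clip(amp * r, 0.0, 1.0)
        if height < thr:
            height = 0.0
        stripes += height * _bump(x, c, w)
        coverage += pr * _bump(x, c, 2.0 * spec.wavelength)
    stripes = np.clip(stripes, 0.0, 1.0)
    if spec.phases[gene] > 0:
        return stripes
    return np.clip(np.clip(coverage, 0, 1) - stripes, 0.0, 1.0)


def synth_profile_series(spec: SyntheticCohortSpec):
    """A staged cohort of expression profiles plus the ground-truth table.

    Returns (profiles, truth) where profiles is a list of ExpressionProfile
    (one per specimen and gene) and truth a DataFrame with one row per
    specimen (age, anchors, weight, stripe centres) and the per-gene lags.
    """
    rng = np.random.default_rng(spec.seed)
    ages = np.sort(rng.uniform(*spec.age_range, spec.n_specimens))
    profiles, rows = [], []
    for i, age in enumerate(ages):
        sid = f"S{i:03d}"
        for gene in spec.genes:
            profiles.append(_specimen_profile(spec, rng, age, gene, sid))
        centres = spec.stripe_positions(age)
        rows.append(
            {
                "specimen_id": sid,
                "age": age,
                "ruga3": float(centres.max()),
                "ruga8": 0.0,
                "d38": float(centres.max()),
                "n_stripes": len(centres),
                "weight_mg": profiles[-1].weight_mg,
                "stripe_centres": ",".join(f"{c:.1f}" for c in centres),
            }
        )
    truth = pd.DataFrame(rows)
    truth.attrs["lags"] = dict(spec.lags)
    truth.attrs["phases"] = dict(spec.phases)
    truth.attrs["stripe_width"] = spec.stripe_width
    return profiles, truth


def synth_contralateral_pair(
    spec: SyntheticCohortSpec,
    effect: dict,
    age: float = None,
    gene: str = "Shh",
    seed=None,
):
    """A (treated, control) shelf pair with a pathway-specific effect.

    ``effect`` keys: ``width_change`` and ``intensity_change`` (fractional),
    ``detection_threshold`` (stripes whose effective height falls below it
    disappear).  Returns (treated, control, truth dict).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    if age is None:
        age = float(np.mean(spec.age_range))
    control = _specimen_profile(spec, rng, age, gene, "ctrl")
    treated = _specimen_profile(spec, rng, age, gene, "trt", effect=effect)
    truth = {
        "age": age,
        "stripe_centres": spec.stripe_positions(age),
        "effect": dict(effect),
        "control_width": spec.stripe_width,
        "treated_width": spec.stripe_width * (1.0 + effect.get("width_change", 0.0)),
    }
    return treated, control, truth


def synth_parameter_library(topology: SignedTopology, n: int, seed=0):
    """n random parameter sets with their DDI classification, reproducible
    by seed.  Returns (list of parameter sets, DataFrame of annotations)."""
    rng = np.random.default_rng(seed)
    sets, rows = [], []
    for i in range(n):
        p = sample_parameter_set(topology, rng)
        cls = classify_ddi(p)
        sets.append(p)
        rows.append(
            {
                "index": i,
                "ddi": cls["ddi"],
                "oscillatory": cls["oscillatory"],
                "phase": None if cls["phase"] is None else "".join(
                    "+" if s > 0 else "-" for s in cls["phase"]
                ),
                "wavelength": cls["wavelength"],
                "growth_rate": cls["growth_rate"],
            }
        )
    return sets, pd.DataFrame(rows)
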