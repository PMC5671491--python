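"""Two-endmember GDGT mixing simulator.

Generates synthetic salinity-transect datasets in which the isoprenoid
GDGT pool of every sample is a linear mixture of:

- a **thaumarchaeotal endmember** constructed to sit exactly on the
  RI-TEX86 core-top calibration at a target temperature (so TEX86 inverts
  to that temperature and the calibration-zone offset is zero), and
- an **MG-II Euryarchaeota endmember** enriched in GDGTs with 1-4
  cyclopentane rings and containing no crenarchaeol — encoding the working
  hypothesis that MG-II produce ringed GDGTs but are not a significant
  crenarchaeol source.  Its composition is a modeling assumption, not a
  measurement: no pure culture exists to constrain it.

The mixing fraction f is simultaneously MG-II's share of the GDGT pool and
its share of 16S copies; lipid-per-cell and gene-copy-number disparities
are deliberately folded into the qPCR noise term.  Noise: per-pool
Dirichlet resampling of the mixture composition (concentration parameter
``dirichlet_concentration``; larger = less noise) and lognormal qPCR error
(``qpcr_sigma_log10``).  All draws derive from one seed via independent
substreams, so a run is fully reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dataset import Dataset, GDGTProfile, SampleRecord
from .screen import CalibrationParams, predicted_ri

__all__ = [
    "ThaumEndmemberSpec",
    "MGIIEndmemberSpec",
    "TransectConfig",
    "EndmemberError",
    "thaum_endmember",
    "mgii_endmember",
    "mix_profiles",
    "simulate_transect",
]


class EndmemberError(ValueError):
    """An endmember specification is infeasible (negative abundance)."""


@dataclass(frozen=True)
class ThaumEndmemberSpec:
    """Construction targets for the on-calibration thaumarchaeotal pool.

    ``temperature`` (°C) fixes the TEX86 target through the inverse
    calibration; ``tex_pool_share`` is the percent of the profile
    allocated to the TEX86 denominator compounds (GDGT-1/2/3 + Cren');
    ``numerator_weights`` split the TEX86 numerator among (GDGT-2, GDGT-3,
    Cren'); ``g4_share`` is the percent given to GDGT-4.  Crenarchaeol
    then solves the ring-index calibration equation and GDGT-0 takes the
    remainder.  Default temperature is a coastal annual-mean sea-surface
    value typical of the subtropical settings the proxy targets.
    """

    temperature: float = 24.7
    tex_pool_share: float = 30.0
    numerator_weights: tuple[float, float, float] = (0.55, 0.25, 0.20)
    g4_share: float = 0.5

    def __post_init__(self) -> None:
        w = self.numerator_weights
        if len(w) != 3 or any(x < 0 for x in w) or abs(sum(w) - 1) > 1e-9:
            raise ValueError("numerator_weights must be 3 nonnegative values summing to 1")
        if not 0 < self.tex_pool_share < 100:
            raise ValueError("tex_pool_share must be in (0, 100)")
        if not 0 <= self.g4_share < 100:
            raise ValueError("g4_share must be in [0, 100)")


@dataclass(frozen=True)
class MGIIEndmemberSpec:
    """Assumed MG-II GDGT composition: ring weights over GDGT-0..4.

    ``ring_weights`` apportion the profile over (GDGT-0..GDGT-4);
    ``cren_iso_share`` (percent) is carved out for the crenarchaeol
    regioisomer.  Crenarchaeol itself is always zero.
    """

    ring_weights: tuple[float, ...] = (0.20, 0.35, 0.20, 0.15, 0.10)
    cren_iso_share: float = 0.0

    def __post_init__(self) -> None:
        w = self.ring_weights
        if len(w) != 5 or any(x < 0 for x in w) or abs(sum(w) - 1) > 1e-9:
            raise ValueError("ring_weights must be 5 nonnegative values summing to 1")
        if not 0 <= self.cren_iso_share < 100:
            raise ValueError("cren_iso_share must be in [0, 100)")


@dataclass(frozen=True)
class TransectConfig:
    """Sampling design and noise levels for a simulated transect.

    ``f_values`` are per-sample MG-II mixing fractions in [0, 1); when
    None, ``n_samples`` points evenly spaced on [0, 0.4] are used (the
    enrichment range yielding estuary-like gene ratios).
    ``dirichlet_concentration`` may be ``inf`` to switch compositional
    noise off; ``qpcr_sigma_log10 = 0`` switches gene-abundance noise off.
    """

    n_samples: int = 50
    f_values: tuple[float, ...] | None = None
    archaea_mean_log10: float = 9.0
    dirichlet_concentration: float = 500.0
    qpcr_sigma_log10: float = 0.1
    seed: int = 0

    def resolved_f(self) -> np.ndarray:
        if self.f_values is None:
            f = np.linspace(0.0, 0.4, self.n_samples)
        else:
            f = np.asarray(self.f_values, dtype=float)
            if f.size != self.n_samples:
                raise ValueError("n_samples must equal len(f_values)")
        if np.any((f < 0) | (f >= 1)):
            raise ValueError("mixing fractions must lie in [0, 1)")
        return f


_FIELDS = ("g0", "g1", "g2", "g3", "g4", "cren", "cren_iso")


def thaum_endmember(
    spec: ThaumEndmemberSpec = ThaumEndmemberSpec(),
    cal: CalibrationParams = CalibrationParams(),
) -> GDGTProfile:
    """Profile with TEX86 inverting to ``spec.temperature`` and ΔRI = 0.

    Solves the construction exactly: the TEX86 target fixes GDGT-1/2/3 and
    Cren' within ``tex_pool_share``; crenarchaeol is then chosen so the
    crenarchaeol-weighted ring index equals the calibration parabola at
    the TEX86 target; GDGT-0 absorbs the remainder.  Raises
    :class:`EndmemberError` naming the violated field when the targets are
    infeasible (e.g. extreme shares leaving negative crenarchaeol or
    GDGT-0).
    """
    t = cal.inverse_temperature(spec.temperature)
    if not 0 < t <= 1:
        raise EndmemberError(
            f"temperature {spec.temperature} °C maps to TEX86 {t:.4g} outside (0, 1]"
        )
    s = spec.tex_pool_share
    w2, w3, wc = spec.numerator_weights
    g1 = (1 - t) * s
    g2, g3, ci = t * s * w2, t * s * w3, t * s * wc
    g4 = spec.g4_share
    cren = (100.0 * predicted_ri(t, cal) - g1 - 2 * g2 - 3 * g3 - 4 * ci) / 4.0
    g0 = 100.0 - (g1 + g2 + g3 + g4 + cren + ci)
    prof = GDGTProfile(g0=g0, g1=g1, g2=g2, g3=g3, g4=g4, cren=cren, cren_iso=ci)
    for name in _FIELDS:
        if getattr(prof, name) < 0:
            raise EndmemberError(
                f"infeasible endmember spec: {name} = {getattr(prof, name):.4g} < 0"
            )
    return prof


def mgii_endmember(spec: MGIIEndmemberSpec = MGIIEndmemberSpec()) -> GDGTProfile:
    """Crenarchaeol-free profile from the assumed MG-II ring weights."""
    ci = spec.cren_iso_share
    rest = 100.0 - ci
    g0, g1, g2, g3, g4 = (rest * w for w in spec.ring_weights)
    return GDGTProfile(g0=g0, g1=g1, g2=g2, g3=g3, g4=g4, cren=0.0, cren_iso=ci)


def mix_profiles(f: float, thaum: GDGTProfile, mgii: GDGTProfile) -> GDGTProfile:
    """Componentwise linear mixture (1-f)*thaum + f*mgii."""
    if not 0 <= f <= 1:
        raise ValueError("mixing fraction must be in [0, 1]")
    return GDGTProfile(
        *((1 - f) * a + f * b for a, b in zip(thaum.as_tuple(), mgii.as_tuple()))
    )


def _dirichlet_around(mean: np.ndarray, concentration: float, rng) -> np.ndarray:
    """Dirichlet draw with the given mean composition (percent scale).

    Components that are exactly zero in the mean stay zero (a Dirichlet
    has no mass to give a zero-alpha component).
    """
    if math.isinf(concentration):
        return mean.copy()
    pos = mean > 0
    alpha = concentration * mean[pos] / 100.0
    out = np.zeros_like(mean)
    out[pos] = 100.0 * rng.dirichlet(alpha)
    return out


def simulate_transect(
    cfg: TransectConfig = TransectConfig(),
    thaum: ThaumEndmemberSpec = ThaumEndmemberSpec(),
    mgii: MGIIEndmemberSpec = MGIIEndmemberSpec(),
    cal: CalibrationParams = CalibrationParams(),
) -> Dataset:
    """Simulate a salinity-gradient transect dataset.

    Per sample i with mixing fraction f_i: the three lipid pools (CL,
    total-IPL, phospho-IPL) each receive an independent compositional-noise
    draw around the same noiseless mixture; archaeal 16S copies are
    lognormal around ``archaea_mean_log10``; MG-II copies are
    f_i * archaea with independent lognormal error, so in the noiseless
    limit the measured gene ratio equals f_i exactly.  Salinity ramps
    linearly from 0 to 33 along the transect and sets the water-type
    label.  The true mixing fraction is stored in ``record.extra["f"]``.
    """
    from .dataset import POOLS  # local to avoid circularity at import time

    f = cfg.resolved_f()
    th = thaum_endmember(thaum, cal)
    mg = mgii_endmember(mgii)

    # independent, deterministic substreams: one for qPCR, one per pool
    ss = np.random.SeedSequence(cfg.seed)
    qpcr_rng, *pool_rngs = (np.random.default_rng(s) for s in ss.spawn(1 + len(POOLS)))

    n = f.size
    salinity = np.linspace(0.0, 33.0, n) if n > 1 else np.array([16.5])
    records = []
    for i in range(n):
        mixture = np.asarray(mix_profiles(float(f[i]), th, mg).as_tuple())
        profiles = {
            pool: GDGTProfile(*_dirichlet_around(mixture, cfg.dirichlet_concentration, rng))
            for pool, rng in zip(POOLS, pool_rngs)
        }
        log_arch = cfg.archaea_mean_log10 + cfg.qpcr_sigma_log10 * qpcr_rng.standard_normal()
        archaea = 10.0 ** log_arch
        mgii_copies = (
            f[i] * archaea * 10.0 ** (cfg.qpcr_sigma_log10 * qpcr_rng.standard_normal())
        )
        sal = float(salinity[i])
        water_type = "river" if sal < 1 else ("sea" if sal > 30 else "mixing")
        records.append(
            SampleRecord(
                sample_id=f"T{i + 1:03d}",
                station=f"T{i + 1:03d}",
                water_type=water_type,
                depth=1.5,
                temperature=thaum.temperature,
                salinity=sal,
                profiles=profiles,
                archaea_16s=float(archaea),
                mgii_16s=float(mgii_copies),
                extra={"f": float(f[i])},
            )
        )
    return Dataset(records, provenance=f"simulated transect (seed={cfg.seed})")
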