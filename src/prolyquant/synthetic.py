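"""Seed-deterministic synthetic-data generators with known ground truth.

Every generator returns its data together with a :class:`SyntheticTruth`
record holding the exact parameters and seed, so parameter-recovery tests are
self-contained: simulate, analyze, compare against the recorded truth.

Noise models: multiplicative Gaussian (coefficient-of-variation style) for
NMR peak volumes, additive Gaussian baseline noise for mass spectra, and
Poisson shot noise plus additive Gaussian read noise for fluorescence images.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exchange import DEFAULT_MIXING_TIMES_S, MixingSeries
from .nativems import MassSpectrum, Species, theoretical_mz

__all__ = [
    "SyntheticTruth",
    "gen_exsy_series",
    "gen_ms_spectrum",
    "gen_foci_image",
    "gen_survival_table",
    "DEFAULT_CHARGE_PROFILE",
]


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth sidecar for a synthetic dataset."""

    generator: str
    parameters: dict = field(default_factory=dict)
    seed: int | None = None

    def to_json(self) -> str:
        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(f"not JSON serializable: {type(o)}")

        return json.dumps(dataclasses.asdict(self), indent=2, default=_default,
                          sort_keys=True)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json() + "\n")


# ---------------------------------------------------------------- EXSY ------

def gen_exsy_series(
    k_ct: float,
    k_tc: float,
    R1: float = 1.0,
    amplitude: float = 1e6,
    t_mix=DEFAULT_MIXING_TIMES_S,
    noise_cv: float = 0.0,
    seed: int | None = None,
    label: str = "synthetic",
) -> tuple[MixingSeries, SyntheticTruth]:
    """Simulate EXSY diagonal and cross-peak volumes over a mixing-time series.

    With equilibrium populations p_t = k_ct/k_ex and p_c = k_tc/k_ex
    (k_ex = k_ct + k_tc), two-site exchange with a shared auto-relaxation
    rate R1 gives the magnetization transfer amplitudes

        I_tt = A p_t (p_t + p_c e^{-k_ex t}) e^{-R1 t}
        I_ct = A p_t p_c (1 - e^{-k_ex t}) e^{-R1 t}

    so the I_ct/I_tt ratio is exactly the two-site build-up law for any R1
    (relaxation cancels).  Multiplicative Gaussian noise with coefficient of
    variation ``noise_cv`` perturbs each volume; the sigma columns carry
    ``noise_cv`` times the noiseless volume.
    """
    if not (k_ct > 0 and k_tc > 0 and R1 > 0 and amplitude > 0):
        raise ValueError("k_ct, k_tc, R1 and amplitude must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    t = np.asarray(t_mix, dtype=float)
    k_ex = k_ct + k_tc
    p_t = k_ct / k_ex
    p_c = k_tc / k_ex
    decay = np.exp(-R1 * t)
    e = np.exp(-k_ex * t)
    I_tt = amplitude * p_t * (p_t + p_c * e) * decay
    I_ct = amplitude * p_t * p_c * (1.0 - e) * decay
    sigma_tt = noise_cv * I_tt
    sigma_ct = noise_cv * I_ct
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        I_tt = I_tt * (1.0 + noise_cv * rng.standard_normal(t.size))
        I_ct = I_ct * (1.0 + noise_cv * rng.standard_normal(t.size))
        I_tt = np.clip(I_tt, 0.0, None)
        I_ct = np.clip(I_ct, 0.0, None)
    series = MixingSeries(
        t_mix=t, I_tt=I_tt, I_ct=I_ct, sigma_tt=sigma_tt, sigma_ct=sigma_ct,
        label=label,
    )
    truth = SyntheticTruth(
        generator="gen_exsy_series",
        parameters={
            "k_ct": k_ct, "k_tc": k_tc, "k_ex": k_ex, "R1": R1,
            "amplitude": amplitude, "t_mix_s": t.tolist(), "noise_cv": noise_cv,
        },
        seed=seed,
    )
    return series, truth


# ------------------------------------------------------------- native MS ----

#: Default native-like charge-state envelope for an ~18 kDa protein.
DEFAULT_CHARGE_PROFILE: dict[int, float] = {6: 0.15, 7: 0.4, 8: 0.3, 9: 0.15}


def gen_ms_spectrum(
    species_abundances: list[tuple[Species, float]],
    charge_profile: dict[int, float] | None = None,
    resolution_sigma: float = 1.0,
    noise_sd: float = 0.0,
    mz_range: tuple[float, float] = (500.0, 6000.0),
    mz_step: float = 0.25,
    scale: float = 1e5,
    seed: int | None = None,
) -> tuple[MassSpectrum, SyntheticTruth]:
    """Simulate a native mass spectrum from true species abundances.

    Each (species, charge) contributes a Gaussian peak at its theoretical m/z
    whose height h_n = abundance * scale * w_n * n (with envelope weights w_n
    normalized to 1) so that the charge-normalized sum over the envelope,
    sum_n h_n / n, equals abundance * scale exactly.  Additive Gaussian
    baseline noise of standard deviation ``noise_sd`` is applied everywhere.
    Peaks falling outside ``mz_range`` are dropped with a warning.
    """
    import warnings as _warnings

    if not species_abundances:
        raise ValueError("at least one species is required")
    profile = dict(charge_profile or DEFAULT_CHARGE_PROFILE)
    if any(w < 0 for w in profile.values()) or sum(profile.values()) <= 0:
        raise ValueError("charge-profile weights must be non-negative, not all zero")
    wsum = sum(profile.values())
    profile = {z: w / wsum for z, w in profile.items()}

    lo, hi = mz_range
    mz = np.arange(lo, hi + mz_step, mz_step)
    y = np.zeros_like(mz)
    peak_records = []
    for sp, abundance in species_abundances:
        if abundance < 0:
            raise ValueError("abundances must be non-negative")
        for z, w in profile.items():
            if w == 0:
                continue
            pos = theoretical_mz(sp.neutral_mass, z)
            if not (lo <= pos <= hi):
                _warnings.warn(
                    f"{sp.name} at {z}+ (m/z {pos:.1f}) falls outside the "
                    f"{lo}-{hi} m/z range and was dropped"
                )
                continue
            height = abundance * scale * w * z
            y += height * np.exp(-0.5 * ((mz - pos) / resolution_sigma) ** 2)
            peak_records.append(
                {"species": sp.name, "charge": z, "mz": pos, "height": height}
            )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = np.clip(y + rng.normal(scale=noise_sd, size=y.size), 0.0, None)
    spectrum = MassSpectrum(mz=mz, intensity=y, metadata={"synthetic": True})
    truth = SyntheticTruth(
        generator="gen_ms_spectrum",
        parameters={
            "abundances": {sp.name: ab for sp, ab in species_abundances},
            "species_masses": {sp.name: sp.neutral_mass for sp, _ in species_abundances},
            "charge_profile": {str(z): w for z, w in profile.items()},
            "resolution_sigma": resolution_sigma,
            "noise_sd": noise_sd,
            "scale": scale,
            "peaks": peak_records,
        },
        seed=seed,
    )
    return spectrum, truth


# ---------------------------------------------------------------- imaging ---

def gen_foci_image(
    n_nuclei: int = 5,
    nucleus_radius: float = 12.0,
    nucleus_intensity: float = 3000.0,
    foci_per_nucleus: int = 5,
    focus_intensity: float = 2000.0,
    background: float = 100.0,
    noise_sd: float = 0.0,
    image_size: int = 256,
    focus_sigma: float = 1.5,
    seed: int | None = None,
    max_tries: int = 2000,
) -> tuple[np.ndarray, SyntheticTruth]:
    """Simulate a two-channel fluorescence field of nuclei with marker foci.

    Channel 0 (DNA stain) holds bright disks on a flat background; channel 1
    (marker) holds small Gaussian foci confined to nuclei.  Nucleus centers
    are placed by rejection sampling so disks do not touch; if placement fails
    after ``max_tries`` attempts an error suggests reducing ``n_nuclei``.
    When ``noise_sd > 0``, Poisson shot noise is applied to the noiseless
    signal and Gaussian read noise of standard deviation ``noise_sd`` added;
    ``noise_sd = 0`` yields the exact noiseless image.  The truth records the
    centers and each nucleus's true integrated marker signal above background.
    """
    rng = np.random.default_rng(seed)
    H = W = int(image_size)
    dna = np.full((H, W), background, dtype=float)
    marker = np.full((H, W), background, dtype=float)
    yy, xx = np.mgrid[0:H, 0:W]

    centers: list[tuple[float, float]] = []
    margin = nucleus_radius + 3
    tries = 0
    while len(centers) < n_nuclei:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n_nuclei} non-overlapping nuclei of radius "
                f"{nucleus_radius} in a {H}x{W} image; try fewer nuclei"
            )
        c = (rng.uniform(margin, H - margin), rng.uniform(margin, W - margin))
        if all(np.hypot(c[0] - a, c[1] - b) > 2 * nucleus_radius + 6
               for a, b in centers):
            centers.append(c)

    per_nucleus_signal = []
    foci_records = []
    for nid, (cy, cx) in enumerate(centers, start=1):
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= nucleus_radius**2
        dna[disk] += nucleus_intensity
        total = 0.0
        for _ in range(foci_per_nucleus):
            rho = rng.uniform(0, 0.6 * nucleus_radius)
            ang = rng.uniform(0, 2 * np.pi)
            fy, fx = cy + rho * np.sin(ang), cx + rho * np.cos(ang)
            blob = focus_intensity * np.exp(
                -0.5 * (((yy - fy) / focus_sigma) ** 2 + ((xx - fx) / focus_sigma) ** 2)
            )
            marker += blob
            total += float(blob[disk].sum())
            foci_records.append({"nucleus_id": nid, "y": fy, "x": fx})
        per_nucleus_signal.append(total)

    if noise_sd > 0:
        dna = rng.poisson(np.clip(dna, 0, None)).astype(float)
        marker = rng.poisson(np.clip(marker, 0, None)).astype(float)
        dna += rng.normal(scale=noise_sd, size=dna.shape)
        marker += rng.normal(scale=noise_sd, size=marker.shape)
        dna = np.clip(dna, 0, None)
        marker = np.clip(marker, 0, None)

    image = np.stack([dna, marker])
    truth = SyntheticTruth(
        generator="gen_foci_image",
        parameters={
            "n_nuclei": n_nuclei,
            "nucleus_radius": nucleus_radius,
            "nucleus_intensity": nucleus_intensity,
            "foci_per_nucleus": foci_per_nucleus,
            "focus_intensity": focus_intensity,
            "background": background,
            "noise_sd": noise_sd,
            "image_size": image_size,
            "centers": [list(c) for c in centers],
            "foci": foci_records,
            "true_integrated_marker": per_nucleus_signal,
        },
        seed=seed,
    )
    return image, truth


# ---------------------------------------------------------------- survival --

def gen_survival_table(
    true_survival: dict[float, float],
    cells_seeded: int = 10000,
    plating_efficiency: float = 0.5,
    seed: int | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate colony counts for a dose series from a known survival curve.

    Colonies at each dose are binomial(cells_seeded, plating_efficiency *
    survival(dose)); the dose-0 entry is the matched untreated reference and
    must be present (added with survival 1.0 if missing).
    """
    if cells_seeded <= 0:
        raise ValueError("cells_seeded must be positive")
    if not (0 < plating_efficiency <= 1):
        raise ValueError("plating efficiency must be in (0, 1]")
    curve = dict(true_survival)
    if 0 not in curve and 0.0 not in curve:
        curve[0.0] = 1.0
    for d, s in curve.items():
        if not (0 < s <= 1):
            raise ValueError(f"survival fraction at dose {d} must be in (0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for dose in sorted(curve):
        p = plating_efficiency * curve[dose]
        rows.append(
            {
                "dose": float(dose),
                "colonies": int(rng.binomial(cells_seeded, p)),
                "cells_seeded": int(cells_seeded),
            }
        )
    table = pd.DataFrame(rows)
    truth = SyntheticTruth(
        generator="gen_survival_table",
        parameters={
            "true_survival": {str(d): s for d, s in sorted(curve.items())},
            "cells_seeded": cells_seeded,
            "plating_efficiency": plating_efficiency,
        },
        seed=seed,
    )
    return table, truth
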