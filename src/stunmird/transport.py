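"""Absorbed fractions and the thyroid self S-value.

The self S-value (absorbed dose per decay, Gy·Bq⁻¹·s⁻¹) of a small organ for
:sup:`99m`Tc is dominated by conversion and Auger electrons; the 140.5 keV
gamma contributes little because a millimetre-scale organ is nearly
transparent to it.  The transport model reflects that split:

* electrons follow straight continuous-slowing-down tracks of tabulated CSDA
  range, depositing energy uniformly along the track; the absorbed fraction
  is the expected in-organ path fraction, estimated by seeded Monte Carlo
  over emission points (uniform per thyroid voxel) and isotropic directions;
* photons use the analytic thin-absorber estimate 1 − exp(−μ_en·ℓ̄) with ℓ̄
  the mean chord length 4V/S of the organ.

Electron lines whose range is far below the organ size deposit locally
(absorbed fraction 1); this is exact to a few parts in 10⁴ for the Auger and
low-energy conversion lines of Tc-99m and keeps 10⁶-history runs fast.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .emissions import EmissionSpectrum
from .phantom import LABEL_THYROID, VoxelPhantom

__all__ = [
    "SValueResult",
    "TransportError",
    "electron_range_um",
    "electron_absorbed_fraction",
    "photon_absorbed_fraction",
    "self_svalue",
    "KEV_TO_J",
    "DEFAULT_SEED",
]

KEV_TO_J = 1.602176634e-16
#: Documented default seed for all Monte Carlo entry points.
DEFAULT_SEED = 20140324

_N_BATCHES = 20
# Ranges below this fraction of the equivalent radius deposit locally in
# self_svalue(); the neglected escape is <= ~3/16 * ratio ~ 0.2%.
_LOCAL_RANGE_RATIO = 0.01


class TransportError(ValueError):
    """Raised for out-of-table energies and invalid transport arguments."""


def _load_table(fname: str, col: str) -> tuple[np.ndarray, np.ndarray]:
    path = resources.files("stunmird.data") / fname
    rows = []
    header: list[str] = []
    for raw in path.read_text(encoding="utf-8").splitlines():
        text = raw.strip()
        if not text or text.startswith("#"):
            continue
        if not header:
            header = [h.strip() for h in text.split(",")]
            continue
        rows.append([float(x) for x in text.split(",")])
    arr = np.asarray(rows)
    energies = arr[:, header.index("energy_keV")]
    values = arr[:, header.index(col)]
    return energies, values


_RANGE_E: np.ndarray | None = None
_RANGE_R: np.ndarray | None = None
_MUEN_E: np.ndarray | None = None
_MUEN_V: np.ndarray | None = None


def _range_table() -> tuple[np.ndarray, np.ndarray]:
    global _RANGE_E, _RANGE_R
    if _RANGE_E is None:
        _RANGE_E, _RANGE_R = _load_table(
            "electron_csda_soft_tissue.csv", "csda_range_g_cm2"
        )
    return _RANGE_E, _RANGE_R


def _muen_table() -> tuple[np.ndarray, np.ndarray]:
    global _MUEN_E, _MUEN_V
    if _MUEN_E is None:
        _MUEN_E, _MUEN_V = _load_table("photon_muen_soft_tissue.csv", "muen_rho_cm2_g")
    return _MUEN_E, _MUEN_V


def _loglog_interp(x: float, xs: np.ndarray, ys: np.ndarray, what: str) -> float:
    if not xs[0] <= x <= xs[-1]:
        raise TransportError(
            f"{what}: energy {x} keV outside tabulated range [{xs[0]}, {xs[-1]}] keV"
        )
    return float(np.exp(np.interp(np.log(x), np.log(xs), np.log(ys))))


def electron_range_um(energy: float, density: float = 1.05) -> float:
    """CSDA range (micrometres) of an electron of ``energy`` keV in soft tissue."""
    if energy <= 0:
        raise TransportError("electron energy must be > 0")
    r_gcm2 = _loglog_interp(energy, *_range_table(), what="electron CSDA range")
    return r_gcm2 / density * 1e4  # cm -> um


def _isotropic_directions(rng: np.random.Generator, m: int) -> np.ndarray:
    u = 2.0 * rng.random(m) - 1.0
    phi = 2.0 * np.pi * rng.random(m)
    s = np.sqrt(1.0 - u * u)
    return np.column_stack((s * np.cos(phi), s * np.sin(phi), u))


def _track_fractions(
    phantom: VoxelPhantom,
    points_um: np.ndarray,
    dirs: np.ndarray,
    range_um: float,
    n_sub: int,
) -> np.ndarray:
    """In-thyroid path fraction of each straight track (midpoint substeps)."""
    ts = (np.arange(n_sub) + 0.5) * (range_um / n_sub)
    labels = phantom.labels
    shape = np.asarray(labels.shape)
    vox = phantom.voxel_size
    inside = np.zeros(len(points_um))
    # positions (m, n_sub, 3) built axis-wise to bound temporaries
    pos = points_um[:, None, :] + dirs[:, None, :] * ts[None, :, None]
    ijk = np.floor(pos / vox).astype(np.int64)
    valid = np.all((ijk >= 0) & (ijk < shape[None, None, :]), axis=2)
    ijk_clipped = np.clip(ijk, 0, shape[None, None, :] - 1)
    hit = labels[ijk_clipped[..., 0], ijk_clipped[..., 1], ijk_clipped[..., 2]] == LABEL_THYROID
    inside = np.mean(hit & valid, axis=1)
    return inside


def _sample_emission_points(
    phantom: VoxelPhantom, rng: np.random.Generator, m: int
) -> np.ndarray:
    tvox = phantom.thyroid_voxels
    if len(tvox) == 0:
        raise TransportError("phantom has no thyroid voxels")
    pick = rng.integers(0, len(tvox), size=m)
    return (tvox[pick] + rng.random((m, 3))) * phantom.voxel_size


def electron_absorbed_fraction(
    energy: float,
    phantom: VoxelPhantom,
    n: int,
    seed: int = DEFAULT_SEED,
    *,
    n_sub: int | None = None,
) -> tuple[float, float]:
    """Monte Carlo self absorbed fraction for a monoenergetic electron line.

    Emission points are uniform within the thyroid, directions isotropic, and
    each history deposits its energy uniformly along a straight track of CSDA
    range; the absorbed fraction is the mean in-thyroid path fraction.

    Returns
    -------
    (fraction, standard_error):
        Estimated absorbed fraction in [0, 1] and its batch-means standard
        error (20 batches).
    """
    if n < 1:
        raise TransportError("number of histories must be >= 1")
    r0 = electron_range_um(energy, phantom.densities[LABEL_THYROID])
    if n_sub is None:
        n_sub = int(max(16, min(128, np.ceil(8.0 * r0 / phantom.voxel_size))))
    rng = np.random.default_rng(seed)

    n_batches = min(_N_BATCHES, n)
    sizes = np.full(n_batches, n // n_batches)
    sizes[: n % n_batches] += 1
    batch_means = np.empty(n_batches)
    for b, m in enumerate(sizes):
        pts = _sample_emission_points(phantom, rng, int(m))
        dirs = _isotropic_directions(rng, int(m))
        batch_means[b] = _track_fractions(phantom, pts, dirs, r0, n_sub).mean()
    frac = float(np.average(batch_means, weights=sizes))
    se = (
        float(np.std(batch_means, ddof=1) / np.sqrt(n_batches))
        if n_batches > 1
        else 0.0
    )
    return frac, se


def photon_absorbed_fraction(energy: float, phantom: VoxelPhantom) -> float:
    """Analytic photon self absorbed fraction 1 − exp(−μ_en·ℓ̄).

    ℓ̄ is the mean chord length 4V/S of the thyroid's volume-equivalent
    sphere; valid in the thin-absorber regime that applies to any
    millimetre-scale organ above ~10 keV.
    """
    if phantom.thyroid_volume_mm3 == 0.0:
        return 0.0
    muen_rho = _loglog_interp(energy, *_muen_table(), what="photon mu_en/rho")
    mu_cm = muen_rho * phantom.densities[LABEL_THYROID]
    chord_cm = phantom.thyroid_mean_chord_mm() * 0.1
    return float(1.0 - np.exp(-mu_cm * chord_cm))


@dataclass(frozen=True)
class SValueResult:
    """Self S-value estimate with its Monte Carlo uncertainty.

    ``electron_fraction`` is the share of the absorbed energy contributed by
    electron lines; for Tc-99m in a milligram-scale thyroid it exceeds 0.9.
    """

    s_value: float  # Gy / (Bq s)
    relative_se: float
    n_histories: int
    electron_fraction: float
    seed: int

    def __post_init__(self) -> None:
        if not self.s_value > 0:
            raise ValueError("s_value must be > 0")
        if self.relative_se < 0:
            raise ValueError("relative_se must be >= 0")
        if not 0.0 <= self.electron_fraction <= 1.0:
            raise ValueError("electron_fraction must be in [0, 1]")


def self_svalue(
    phantom: VoxelPhantom,
    spectrum: EmissionSpectrum,
    n: int = 10**6,
    seed: int = DEFAULT_SEED,
    *,
    assume_local: bool = False,
) -> SValueResult:
    """Thyroid self S-value: S = Σ yᵢ·Eᵢ·φ(Eᵢ) / m.

    Electron absorbed fractions come from the seeded straight-track Monte
    Carlo (``n`` histories per transported line; lines with range ≪ organ
    radius deposit locally), photon fractions from the analytic mean-chord
    model.  The relative standard error is computed from 20 equal batches.

    Parameters
    ----------
    assume_local:
        Force every electron absorbed fraction to exactly 1 and skip photons'
        transport entirely — the closed-form local-deposition limit
        S = Δ_electron·(1.602e−16 J/keV)/m used for verification.
    """
    if n < 10**3:
        raise TransportError("need at least 1e3 histories for a reported SE")
    e_lines = spectrum.electron_lines()
    p_lines = spectrum.photon_lines()
    if not e_lines and not p_lines:
        raise TransportError("spectrum has no lines")

    mass_kg = phantom.thyroid_mass * 1e-6
    if mass_kg <= 0:
        raise TransportError("phantom thyroid mass must be > 0")
    scale = KEV_TO_J / mass_kg  # keV/decay -> Gy per (Bq s)

    if assume_local:
        s_e = sum(ln.yield_ * ln.energy for ln in e_lines) * scale
        return SValueResult(
            s_value=float(s_e),
            relative_se=0.0,
            n_histories=n,
            electron_fraction=1.0,
            seed=seed,
        )

    r_equiv_um = phantom.thyroid_equivalent_radius_mm * 1e3
    density = phantom.densities[LABEL_THYROID]

    local_kev = 0.0
    transported: list = []
    for ln in e_lines:
        r0 = electron_range_um(ln.energy, density)
        if r0 < _LOCAL_RANGE_RATIO * r_equiv_um:
            local_kev += ln.yield_ * ln.energy
        else:
            transported.append(ln)

    photon_kev = sum(
        ln.yield_ * ln.energy * photon_absorbed_fraction(ln.energy, phantom)
        for ln in p_lines
    )

    # one child seed stream per transported line, all derived from `seed`
    children = np.random.SeedSequence(seed).spawn(max(1, len(transported)))
    n_batches = min(_N_BATCHES, n)
    sizes = np.full(n_batches, n // n_batches)
    sizes[: n % n_batches] += 1

    batch_kev = np.full(n_batches, local_kev + photon_kev)
    absorbed_e_kev = local_kev
    for ln, child in zip(transported, children):
        rng = np.random.default_rng(child)
        r0 = electron_range_um(ln.energy, density)
        n_sub = int(max(16, min(128, np.ceil(8.0 * r0 / phantom.voxel_size))))
        line_means = np.empty(n_batches)
        for b, m in enumerate(sizes):
            pts = _sample_emission_points(phantom, rng, int(m))
            dirs = _isotropic_directions(rng, int(m))
            line_means[b] = _track_fractions(phantom, pts, dirs, r0, n_sub).mean()
        batch_kev += ln.yield_ * ln.energy * line_means
        absorbed_e_kev += ln.yield_ * ln.energy * float(
            np.average(line_means, weights=sizes)
        )

    total_kev = float(np.average(batch_kev, weights=sizes))
    s_value = total_kev * scale
    se_kev = (
        float(np.std(batch_kev, ddof=1) / np.sqrt(n_batches)) if n_batches > 1 else 0.0
    )
    rel_se = se_kev / total_kev if total_kev > 0 else 0.0
    efrac = absorbed_e_kev / total_kev if total_kev > 0 else 0.0
    return SValueResult(
        s_value=float(s_value),
        relative_se=float(rel_se),
        n_histories=n,
        electron_fraction=float(min(1.0, efrac)),
        seed=seed,
    )
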