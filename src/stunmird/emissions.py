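"""Radionuclide emission spectra.

A decay of :sup:`99m`Tc releases a mixture of photons (the 140.5 keV gamma
plus K/L X-rays) and electrons (conversion electrons of the 2.17, 140.5 and
142.6 keV transitions plus Auger cascades).  For dosimetry all that matters
is the list of (type, energy, yield) lines and the physical half-life; both
are shipped as a plain-text table and parsed into an
:class:`EmissionSpectrum`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

__all__ = [
    "EmissionLine",
    "EmissionSpectrum",
    "EmissionTableError",
    "load_emission_spectrum",
    "TC99M_HALF_LIFE_H",
]

#: Physical half-life of Tc-99m in hours (decay-data compilations; also the
#: value carried in the packaged emission-table header).
TC99M_HALF_LIFE_H = 6.0067

_MAX_YIELD = 5.0  # maximum plausible multiplicity per decay for a single line


class EmissionTableError(ValueError):
    """Raised for malformed emission tables (bad row, missing header)."""


@dataclass(frozen=True)
class EmissionLine:
    """One radiation line: ``kind`` is ``"photon"`` or ``"electron"``,
    ``energy`` in keV, ``yield_`` in emissions per decay."""

    kind: Literal["photon", "electron"]
    energy: float
    yield_: float

    def __post_init__(self) -> None:
        if self.kind not in ("photon", "electron"):
            raise EmissionTableError(f"unknown emission kind {self.kind!r}")
        if not self.energy > 0:
            raise EmissionTableError(f"line energy must be > 0, got {self.energy}")
        if not 0 < self.yield_ <= _MAX_YIELD:
            raise EmissionTableError(
                f"line yield must be in (0, {_MAX_YIELD}], got {self.yield_}"
            )


@dataclass(frozen=True)
class EmissionSpectrum:
    """Per-decay emission lines of one nuclide plus its physical half-life.

    ``delta_electron`` / ``delta_photon`` are the mean emitted energies per
    decay (keV) summed over the electron / photon lines — the MIRD "Delta"
    quantities up to a unit constant.
    """

    nuclide: str
    half_life: float  # hours
    lines: tuple[EmissionLine, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.half_life > 0:
            raise EmissionTableError(f"half-life must be > 0, got {self.half_life}")
        if not self.lines:
            raise EmissionTableError("spectrum must contain at least one line")

    def _sum(self, kind: str) -> float:
        return float(
            sum(ln.yield_ * ln.energy for ln in self.lines if ln.kind == kind)
        )

    @property
    def delta_electron(self) -> float:
        """Mean electron energy emitted per decay (keV)."""
        return self._sum("electron")

    @property
    def delta_photon(self) -> float:
        """Mean photon energy emitted per decay (keV)."""
        return self._sum("photon")

    def electron_lines(self) -> tuple[EmissionLine, ...]:
        return tuple(ln for ln in self.lines if ln.kind == "electron")

    def photon_lines(self) -> tuple[EmissionLine, ...]:
        return tuple(ln for ln in self.lines if ln.kind == "photon")


_HEADER_RE = re.compile(r"#\s*nuclide=(\S+)\s+half_life_h=([0-9.eE+-]+)")


def packaged_emission_table(nuclide: str = "Tc-99m") -> Path:
    """Path of the emission table shipped with the package."""
    name = nuclide.lower().replace("-", "").replace("m", "m")
    fname = {"tc99m": "tc99m_emissions.csv"}.get(name)
    if fname is None:
        raise EmissionTableError(f"no packaged emission table for nuclide {nuclide!r}")
    return Path(str(resources.files("stunmird.data") / fname))


def load_emission_spectrum(
    path: str | Path | None = None,
    *,
    yield_cutoff: float = 1e-6,
) -> EmissionSpectrum:
    """Parse an emission table into an :class:`EmissionSpectrum`.

    The file is comma-separated with columns ``kind,energy_keV,yield`` and a
    comment header line ``# nuclide=<name> half_life_h=<value>``.  Rows whose
    yield falls below ``yield_cutoff`` are retained (the cutoff exists only so
    callers can introspect it); with the default 1e-6 nothing is dropped.

    Parameters
    ----------
    path:
        Table to read; ``None`` loads the packaged Tc-99m table.
    """
    if path is None:
        path = packaged_emission_table()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    nuclide: str | None = None
    half_life: float | None = None
    lines: list[EmissionLine] = []
    saw_column_header = False

    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        text = raw.strip()
        if not text:
            continue
        if text.startswith("#"):
            m = _HEADER_RE.match(text)
            if m:
                nuclide, half_life = m.group(1), float(m.group(2))
            continue
        if not saw_column_header and text.lower().startswith("kind"):
            saw_column_header = True
            continue
        parts = [p.strip() for p in text.split(",")]
        if len(parts) != 3:
            raise EmissionTableError(
                f"{path.name}:{lineno}: expected 3 comma-separated fields, got {len(parts)}"
            )
        kind, e_str, y_str = parts
        try:
            energy, yld = float(e_str), float(y_str)
        except ValueError as exc:
            raise EmissionTableError(
                f"{path.name}:{lineno}: non-numeric energy/yield ({e_str!r}, {y_str!r})"
            ) from exc
        if yld < yield_cutoff:
            # retained by contract; the cutoff only tags negligible lines
            pass
        try:
            lines.append(EmissionLine(kind=kind, energy=energy, yield_=yld))  # type: ignore[arg-type]
        except EmissionTableError as exc:
            raise EmissionTableError(f"{path.name}:{lineno}: {exc}") from exc

    if half_life is None or nuclide is None:
        raise EmissionTableError(
            f"{path.name}: missing '# nuclide=<name> half_life_h=<value>' header"
        )
    if not lines:
        raise EmissionTableError(f"{path.name}: table contains no emission lines")
    return EmissionSpectrum(nuclide=nuclide, half_life=half_life, lines=tuple(lines))


def spectrum_from_lines(
    lines: Iterable[tuple[str, float, float]],
    *,
    nuclide: str = "synthetic",
    half_life: float = TC99M_HALF_LIFE_H,
) -> EmissionSpectrum:
    """Build a spectrum programmatically from ``(kind, energy_keV, yield)`` tuples."""
    return EmissionSpectrum(
        nuclide=nuclide,
        half_life=half_life,
        lines=tuple(EmissionLine(k, e, y) for k, e, y in lines),  # type: ignore[arg-type]
    )
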