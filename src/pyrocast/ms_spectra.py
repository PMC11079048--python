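"""EI-MS spectrum model, JCAMP-DX ingestion and abundance thresholding.

Electron-impact spectra are stored as unit-mass peak lists (m/z rounded to
the nearest integer on ingest; EI reference tables are unit-mass) with
relative abundances normalized so the base peak is 100 %.  A relative-
abundance threshold (default 5 %) removes peaks attributable to instrument
noise or isotope contributions before any matching is done; matching
refuses unthresholded spectra to prevent silent noise matches.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from importlib import resources

from .chem_core import round_half_away

__all__ = [
    "Peak",
    "Spectrum",
    "JcampFormatError",
    "EmptySpectrumError",
    "parse_jcamp",
    "write_jcamp",
    "apply_threshold",
    "base_peak",
    "spectrum_from_pairs",
    "read_peaks_csv",
    "load_fixture_spectrum",
    "DEFAULT_THRESHOLD",
]

DEFAULT_THRESHOLD = 5.0  # percent relative abundance


class JcampFormatError(ValueError):
    """Malformed JCAMP-DX document."""


class EmptySpectrumError(ValueError):
    """Operation requires at least one peak."""


@dataclass(frozen=True, order=True)
class Peak:
    mz: int                 # nominal (unit) mass
    rel_abundance: float    # percent, (0, 100]

    def __post_init__(self):
        if self.mz < 1:
            raise ValueError(f"peak m/z must be >= 1, got {self.mz}")
        if not 0 < self.rel_abundance <= 100:
            raise ValueError(
                f"relative abundance must be in (0, 100], got {self.rel_abundance}")


@dataclass(frozen=True)
class Spectrum:
    """A normalized EI-MS peak list.

    ``threshold_applied`` is None for raw spectra and records the percent
    cut once :func:`apply_threshold` has run.  The molecular ion may be
    absent from the peak list (and may be None if unknown).
    """

    peaks: tuple[Peak, ...]
    molecular_ion_mz: int | None = None
    source_id: str = ""
    threshold_applied: float | None = None

    def __post_init__(self):
        mzs = [p.mz for p in self.peaks]
        if len(set(mzs)) != len(mzs):
            raise ValueError(f"duplicate m/z values in spectrum {self.source_id!r}")
        if self.peaks and abs(max(p.rel_abundance for p in self.peaks) - 100.0) > 1e-9:
            raise ValueError("spectrum not normalized: base peak must be 100")

    @property
    def mz_set(self) -> frozenset[int]:
        return frozenset(p.mz for p in self.peaks)

    def abundance_at(self, mz: int) -> float | None:
        for p in self.peaks:
            if p.mz == mz:
                return p.rel_abundance
        return None


def spectrum_from_pairs(pairs, molecular_ion_mz=None, source_id="",
                        threshold_applied=None) -> Spectrum:
    """Build a normalized spectrum from raw (mz, intensity) pairs.

    m/z values are rounded to nominal mass; intensities at the same
    nominal mass are merged (maximum kept); intensities are rescaled to
    base peak = 100.
    """
    merged: dict[int, float] = {}
    for mz, inten in pairs:
        if inten <= 0:
            continue
        key = round_half_away(float(mz))
        merged[key] = max(merged.get(key, 0.0), float(inten))
    if not merged:
        raise EmptySpectrumError(f"no positive-intensity peaks ({source_id!r})")
    top = max(merged.values())
    peaks = tuple(
        Peak(mz=mz, rel_abundance=100.0 * inten / top)
        for mz, inten in sorted(merged.items())
    )
    return Spectrum(peaks=peaks, molecular_ion_mz=molecular_ion_mz,
                    source_id=source_id, threshold_applied=threshold_applied)


# ---------------------------------------------------------------------------
# JCAMP-DX (peak-table subset)

_PAIR_RE = re.compile(r"([0-9]+(?:\.[0-9]+)?)\s*[,\s]\s*([0-9]+(?:\.[0-9]+)?)")
_DATA_LABELS = ("##PEAK TABLE", "##PEAKTABLE", "##XYDATA")


def parse_jcamp(text: str) -> Spectrum:
    """Parse a JCAMP-DX document containing a ``(XY..XY)`` peak table.

    Supports the ``##PEAK TABLE=(XY..XY)`` and ``##XYDATA=(XY..XY)``
    layouts used by EI reference libraries: whitespace- or semicolon-
    separated ``x,y`` pairs.  Abundances are normalized to base peak 100.
    """
    lines = text.splitlines()
    title = ""
    mw: int | None = None
    pairs: list[tuple[float, float]] = []
    in_table = False
    found_table = False
    for lineno, line in enumerate(lines, 1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("##"):
            upper = stripped.upper()
            in_table = False
            if upper.startswith("##TITLE="):
                title = stripped.split("=", 1)[1].strip()
            elif upper.startswith("##MW="):
                try:
                    mw = round_half_away(float(stripped.split("=", 1)[1]))
                except ValueError as exc:
                    raise JcampFormatError(f"line {lineno}: bad ##MW value") from exc
            elif any(upper.startswith(lbl) for lbl in _DATA_LABELS):
                in_table = True
                found_table = True
                # pairs may follow on the same line after the variable list
                tail = stripped.split("=", 1)[1] if "=" in stripped else ""
                tail = re.sub(r"\(XY\.\.XY\)", "", tail, flags=re.I)
                pairs.extend(_parse_pairs(tail, lineno))
            continue
        if in_table:
            pairs.extend(_parse_pairs(stripped, lineno))
    if not found_table:
        raise JcampFormatError("no ##PEAK TABLE= or ##XYDATA= block found")
    if not pairs:
        raise JcampFormatError("peak table contains no data pairs")
    return spectrum_from_pairs(pairs, molecular_ion_mz=mw, source_id=title)


def _parse_pairs(chunk: str, lineno: int) -> list[tuple[float, float]]:
    chunk = chunk.strip()
    if not chunk:
        return []
    pairs = [(float(x), float(y)) for x, y in _PAIR_RE.findall(chunk)]
    leftover = _PAIR_RE.sub("", chunk).replace(";", " ").strip()
    if leftover:
        raise JcampFormatError(f"line {lineno}: non-numeric peak data {leftover!r}")
    return pairs


def write_jcamp(spec: Spectrum, title: str = "") -> str:
    """Serialize a spectrum to a minimal JCAMP-DX peak-table document."""
    out = [
        f"##TITLE={title or spec.source_id}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=MASS SPECTRUM",
    ]
    if spec.molecular_ion_mz is not None:
        out.append(f"##MW={spec.molecular_ion_mz}")
    out.append(f"##NPOINTS={len(spec.peaks)}")
    out.append("##PEAK TABLE=(XY..XY)")
    out.extend(f"{p.mz},{p.rel_abundance!r}" for p in spec.peaks)
    out.append("##END=")
    return "\n".join(out) + "\n"


def read_peaks_csv(path, molecular_ion_mz=None, source_id="") -> Spectrum:
    """Read an inline CSV peak list with columns ``mz,abundance``."""
    import pandas as pd

    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "mz" not in cols or "abundance" not in cols:
        raise ValueError(f"{path}: expected columns mz,abundance")
    return spectrum_from_pairs(
        zip(df[cols["mz"]], df[cols["abundance"]]),
        molecular_ion_mz=molecular_ion_mz,
        source_id=source_id or str(path),
    )


# ---------------------------------------------------------------------------
# operations

def apply_threshold(spec: Spectrum, t: float = DEFAULT_THRESHOLD) -> Spectrum:
    """Drop peaks below ``t`` percent relative abundance (inclusive keep).

    Idempotent; records the threshold on the returned spectrum.
    """
    if not 0 < t <= 100:
        raise ValueError(f"threshold must be in (0, 100], got {t}")
    kept = tuple(p for p in spec.peaks if p.rel_abundance >= t)
    return replace(spec, peaks=kept, threshold_applied=t)


def base_peak(spec: Spectrum) -> Peak:
    """The most abundant peak; ties broken toward the lowest m/z."""
    if not spec.peaks:
        raise EmptySpectrumError(f"spectrum {spec.source_id!r} has no peaks")
    return max(spec.peaks, key=lambda p: (p.rel_abundance, -p.mz))


def load_fixture_spectrum(name: str) -> Spectrum:
    """Load a packaged JCAMP fixture spectrum by short name."""
    path = resources.files("pyrocast.data").joinpath(f"{name}_ei_ms.jdx")
    return parse_jcamp(path.read_text())
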