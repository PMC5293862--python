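"""NIST MSP spectral-library text I/O.

Blocks look like::

    Name: K-Glc-maGlc
    PrecursorMZ: 697.1611
    Num Peaks: 3
    697.1611 100.0
    449.1083 60.0
    287.0550 80.0

Reading is strict: a ``Num Peaks`` count that disagrees with the number of
ion lines is an error naming the offending line, because silently truncated
libraries are worse than no library.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["Spectrum", "write_msp", "read_msp", "MspError"]


class MspError(ValueError):
    pass


@dataclass
class Spectrum:
    name: str
    precursor_mz: float
    ions: list[tuple[float, float]] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)


def write_msp(spectra: list[Spectrum]) -> str:
    blocks = []
    for s in spectra:
        lines = [f"Name: {s.name}", f"PrecursorMZ: {s.precursor_mz:.4f}"]
        for key, val in s.metadata.items():
            lines.append(f"{key}: {val}")
        lines.append(f"Num Peaks: {len(s.ions)}")
        for mz, inten in s.ions:
            lines.append(f"{mz:.4f} {inten:g}")
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + ("\n" if blocks else "")


def read_msp(text: str) -> list[Spectrum]:
    spectra: list[Spectrum] = []
    name = None
    precursor = None
    meta: dict[str, str] = {}
    ions: list[tuple[float, float]] = []
    declared: int | None = None

    def flush(lineno: int) -> None:
        nonlocal name, precursor, meta, ions, declared
        if name is None and not ions and precursor is None:
            return
        if name is None:
            raise MspError(f"line {lineno}: block without a Name field")
        if declared is None:
            raise MspError(f"line {lineno}: block {name!r} without Num Peaks")
        if declared != len(ions):
            raise MspError(
                f"line {lineno}: block {name!r} declares Num Peaks: {declared} "
                f"but has {len(ions)} ion lines"
            )
        spectra.append(Spectrum(name, precursor if precursor is not None else 0.0,
                                ions, meta))
        name, precursor, meta, ions, declared = None, None, {}, [], None

    for i, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            flush(i)
            continue
        if ":" in line and not line[0].isdigit():
            key, _, val = line.partition(":")
            key, val = key.strip(), val.strip()
            lk = key.lower()
            if lk == "name":
                if name is not None or ions:
                    flush(i)  # new block without blank separator
                name = val
            elif lk == "precursormz":
                try:
                    precursor = float(val)
                except ValueError:
                    raise MspError(f"line {i}: bad PrecursorMZ {val!r}") from None
            elif lk == "num peaks":
                try:
                    declared = int(val)
                except ValueError:
                    raise MspError(f"line {i}: bad Num Peaks {val!r}") from None
            else:
                meta[key] = val
        else:
            parts = line.split()
            if len(parts) != 2:
                raise MspError(f"line {i}: expected 'm/z intensity', got {line!r}")
            try:
                ions.append((float(parts[0]), float(parts[1])))
            except ValueError:
                raise MspError(f"line {i}: non-numeric ion line {line!r}") from None
    flush(len(text.splitlines()) + 1)
    return spectra
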