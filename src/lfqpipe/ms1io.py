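"""Reader/writer for the MS1 text format (msConvert-style precursor scans).

The format is line-oriented: optional ``H`` header lines, then per scan an
``S <number> <number> [precursor]`` line, optional ``I`` info lines (``I
RTime <seconds>`` carries retention time), and whitespace-separated
``m/z intensity`` peak lines.  The reader validates strictly increasing
scan numbers and reports unparseable lines by line number; the writer
produces a canonical form that round-trips byte-identically through
read/write.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class MS1FormatError(ValueError):
    """Raised on a malformed MS1 file (bad line or non-monotone scans)."""


@dataclass
class Scan:
    number: int
    retention_time: float          # seconds; 0 when the file carries none
    mz: np.ndarray                 # ascending within the scan as written
    intensity: np.ndarray


@dataclass
class MS1Run:
    """Ordered precursor scans of one replicate's chromatogram."""

    replicate_id: str
    scans: list[Scan] = field(default_factory=list)

    def scan_index(self, scan_number: int) -> int:
        for i, s in enumerate(self.scans):
            if s.number == scan_number:
                return i
        raise KeyError(f"scan {scan_number} not in run {self.replicate_id!r}")

    @property
    def scan_numbers(self) -> list[int]:
        return [s.number for s in self.scans]


def read_ms1(path, replicate_id: str | None = None) -> MS1Run:
    """Parse an MS1 text file into an MS1Run, preserving peak lists losslessly."""
    if replicate_id is None:
        import os

        replicate_id = os.path.splitext(os.path.basename(str(path)))[0]
    scans: list[Scan] = []
    cur_num: int | None = None
    cur_rt = 0.0
    cur_mz: list[float] = []
    cur_int: list[float] = []

    def flush():
        if cur_num is not None:
            scans.append(
                Scan(cur_num, cur_rt, np.asarray(cur_mz, float), np.asarray(cur_int, float))
            )

    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("H"):
                continue
            if line.startswith("S"):
                flush()
                parts = line.split()
                try:
                    num = int(parts[1])
                except (IndexError, ValueError) as exc:
                    raise MS1FormatError(f"{path}, line {line_no}: bad S line {line!r}") from exc
                if scans and num <= scans[-1].number or cur_num is not None and num <= cur_num:
                    raise MS1FormatError(
                        f"{path}, line {line_no}: scan numbers not strictly increasing at {num}"
                    )
                cur_num, cur_rt, cur_mz, cur_int = num, 0.0, [], []
            elif line.startswith("I"):
                parts = line.split()
                if len(parts) >= 3 and parts[1] == "RTime":
                    try:
                        cur_rt = float(parts[2])
                    except ValueError as exc:
                        raise MS1FormatError(f"{path}, line {line_no}: bad RTime {line!r}") from exc
            else:
                parts = line.split()
                if cur_num is None:
                    raise MS1FormatError(f"{path}, line {line_no}: peak line before any S line")
                try:
                    mz, inten = float(parts[0]), float(parts[1])
                except (IndexError, ValueError) as exc:
                    raise MS1FormatError(
                        f"{path}, line {line_no}: unparseable peak line {line!r}"
                    ) from exc
                cur_mz.append(mz)
                cur_int.append(inten)
    flush()
    return MS1Run(replicate_id=replicate_id, scans=scans)


def write_ms1(run: MS1Run, path) -> None:
    """Write an MS1Run in canonical text form (stable byte-for-byte)."""
    with open(path, "w") as fh:
        fh.write(f"H\tExtractor\tlfqpipe\n")
        for scan in run.scans:
            fh.write(f"S\t{scan.number}\t{scan.number}\n")
            fh.write(f"I\tRTime\t{scan.retention_time!r}\n")
            for mz, inten in zip(scan.mz, scan.intensity):
                fh.write(f"{float(mz)!r} {float(inten)!r}\n")
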