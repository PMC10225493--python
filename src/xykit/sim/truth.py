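"""Machine-readable ground truth emitted by every simulator."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple


@dataclass
class TruthSet:
    """Coordinates are 0-based half-open; sequence intervals are (chrom, start, end)."""

    sdr: Optional[Tuple[str, int, int]] = None
    msr: Optional[Tuple[str, int, int]] = None
    sweep_windows: List[Tuple[str, int, int]] = field(default_factory=list)
    n_fusions: Optional[int] = None
    n_fissions: Optional[int] = None
    efrs: List[Tuple[str, int, int, str]] = field(default_factory=list)
    ltr_age_years: Optional[float] = None

    def validate_bounds(self, chrom_lengths: dict) -> None:
        for iv in filter(None, [self.sdr, self.msr]):
            chrom, s, e = iv
            if not (0 <= s <= e <= chrom_lengths[chrom]):
                raise ValueError(f"truth interval {iv} outside chromosome bounds")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=list) + "\n")

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        raw = json.loads(Path(path).read_text())
        ts = cls()
        for k, v in raw.items():
            if k in ("sdr", "msr") and v is not None:
                v = tuple(v)
            if k == "sweep_windows":
                v = [tuple(x) for x in v]
            if k == "efrs":
                v = [tuple(x) for x in v]
            setattr(ts, k, v)
        return ts

    def write_sweep_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, s, e in self.sweep_windows:
                fh.write(f"{chrom}\t{s}\t{e}\n")
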