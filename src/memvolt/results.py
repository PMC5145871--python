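"""Tabular scan results with unit/policy metadata and TSV round-trip."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd


@dataclass
class ScanResult:
    """A results table plus the metadata needed to interpret it.

    ``metadata`` records units, the charge-closure policy, composition
    and package version; it is written as ``# key: value`` comment lines
    ahead of a plain tab-separated table (no plotting-tool markup).
    """

    table: pd.DataFrame
    metadata: dict[str, Any] = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        from . import __version__

        with open(path, "w") as fh:
            fh.write(f"# memvolt {__version__}\n")
            for key, value in self.metadata.items():
                fh.write(f"# {key}: {value}\n")
            self.table.to_csv(fh, sep="\t", index=False)
        return path

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ScanResult":
        path = Path(path)
        metadata: dict[str, Any] = {}
        with open(path) as fh:
            lines = fh.readlines()
        n_comment = 0
        for line in lines:
            if not line.startswith("#"):
                break
            n_comment += 1
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                metadata[key.strip()] = value.strip()
        table = pd.read_csv(path, sep="\t", skiprows=n_comment)
        return cls(table=table, metadata=metadata)
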