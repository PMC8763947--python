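"""File formats and the in-memory expression container.

Formats handled:

* expression TSV — first column ``gene`` (HGNC symbol), remaining columns
  one per sample; integer counts or 4-decimal transformed values;
* sample metadata TSV — ``sample, histology, prior_best_response, resistant``;
* caliper trial CSV — long format,
  ``animal_id, group, day, length_mm, width_mm, body_weight_g``;
* GMT gene-set files — one set per tab-separated line:
  name, description, member symbols.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

RAW_COUNTS = "raw_counts"
LOG2_NORMALIZED = "log2_normalized"


@dataclass
class ExpressionMatrix:
    """Genes x samples grid with unique HGNC row keys.

    ``scale`` records whether values are raw non-negative integer counts or
    finite log2-normalized expression; the invariants of the declared scale
    are enforced at construction.
    """

    data: pd.DataFrame
    scale: str = RAW_COUNTS

    def __post_init__(self) -> None:
        if self.scale not in (RAW_COUNTS, LOG2_NORMALIZED):
            raise ValueError(f"unknown scale: {self.scale!r}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate gene IDs in expression matrix")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample IDs in expression matrix")
        values = self.data.to_numpy()
        if self.scale == RAW_COUNTS:
            if np.any(values < 0):
                raise ValueError("raw counts must be non-negative")
            if not np.allclose(values, np.round(values)):
                raise ValueError("raw counts must be integers")
        else:
            if not np.all(np.isfinite(values)):
                raise ValueError("log2-normalized values must be finite")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "gene"
        if self.scale == RAW_COUNTS:
            out = out.astype(int)
            out.to_csv(path, sep="\t")
        else:
            out.to_csv(path, sep="\t", float_format="%.4f")

    @classmethod
    def from_tsv(cls, path: str | Path, scale: str = RAW_COUNTS) -> "ExpressionMatrix":
        frame = pd.read_csv(path, sep="\t", index_col="gene")
        return cls(frame, scale=scale)


@dataclass
class _GeneSetRecord:
    """Internal GMT record; the public GeneSet type lives in enrichment."""

    name: str
    description: str
    members: list[str] = field(default_factory=list)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into ``{set name: member symbols}``.

    Duplicate members within a set are dropped, preserving first occurrence.
    """
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (need name, description, members): {line!r}")
        name, members = parts[0], parts[2:]
        sets[name] = list(dict.fromkeys(m for m in members if m))
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "") -> None:
    lines = ["\t".join([name, description, *members]) for name, members in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    if "sample" not in meta.columns:
        raise ValueError("metadata must have a 'sample' column")
    return meta.set_index("sample")


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=True, index_label="sample")


TRIAL_COLUMNS = ["animal_id", "group", "day", "length_mm", "width_mm", "body_weight_g"]


def read_trial(path: str | Path) -> pd.DataFrame:
    trial = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in trial.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    return trial


def write_trial(trial: pd.DataFrame, path: str | Path) -> None:
    trial[TRIAL_COLUMNS].to_csv(path, index=False)
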