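"""Shared association-scan result container.

Every engine returns an :class:`AssociationResult`: one row per marker with
the engine's evidence — p-values (with effect estimate and standard error)
for the frequentist engines, posterior model frequency and per-marker
genetic variance for the Bayesian engine — plus the engine tag that selects
the ranking rule used by the evaluation layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AssociationResult"]


@dataclass
class AssociationResult:
    table: pd.DataFrame
    engine: str
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        need = {"id", "chrom", "pos"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"result table must contain columns {sorted(need)}")
        if self.engine in ("mlm", "glm", "farmcpu"):
            p = self.table["p"].to_numpy(float)
            ok = np.isfinite(p)
            if np.any((p[ok] <= 0) | (p[ok] > 1)):
                raise ValueError("p-values must lie in (0, 1]")
        elif self.engine == "bayescpi":
            mf = self.table["model_frequency"].to_numpy(float)
            if np.any((mf < 0) | (mf > 1)):
                raise ValueError("model frequencies must lie in [0, 1]")
        else:
            raise ValueError(f"unknown engine tag: {self.engine!r}")

    @property
    def n_markers(self) -> int:
        return len(self.table)

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)
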