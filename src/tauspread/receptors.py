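"""Neurotransmission-marker panels, ratio maps and tau associations.

The panel covers 19 markers (15 receptors and 4 transporters) spanning the
serotonergic, dopaminergic, cholinergic, noradrenergic, histaminergic,
cannabinoid, opioid, glutamatergic and GABAergic systems.  Nine derived ratio
maps summarize excitatory/inhibitory balance and transmitter-system balances;
all are elementwise per region and invariant under global rescaling of the
panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

#: The 16 markers entering the ratio formulas.
FORMULA_MARKERS: tuple[str, ...] = (
    "5-HT1A", "5-HT1B", "5-HT2A", "5-HT4", "5-HT6",
    "D1", "D2", "DAT", "NET", "M1", "α4β2", "VAChT",
    "NMDA", "mGluR5", "GABA_A/BZ", "H3",
)

#: Full 19-marker panel: the serotonin transporter completes the four
#: transporters (DAT, NET, VAChT, 5-HTT); CB1 and MOR complete the 15
#: receptors (cannabinoid and opioid systems).
PANEL_MARKERS: tuple[str, ...] = FORMULA_MARKERS + ("5-HTT", "CB1", "MOR")


@dataclass
class ReceptorPanel:
    """Named strictly-positive regional density maps, one per marker."""

    maps: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        lengths = set()
        maps = {}
        for name, values in self.maps.items():
            v = np.asarray(values, dtype=float)
            if np.any(~np.isfinite(v)) or np.any(v <= 0):
                raise ValueError(f"marker {name!r} must be strictly positive and finite")
            maps[name] = v
            lengths.add(v.size)
        if len(lengths) > 1:
            raise ValueError("all marker maps must have identical region counts")
        self.maps = maps

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in self.maps:
            raise KeyError(f"marker {name!r} missing from panel")
        return self.maps[name]

    @property
    def n_regions(self) -> int:
        return next(iter(self.maps.values())).size


#: Ratio formulas as (numerator markers, denominator markers).
RATIO_FORMULAS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "E:I": (
        ("5-HT2A", "5-HT4", "5-HT6", "D1", "M1", "α4β2", "NMDA", "mGluR5"),
        ("5-HT1A", "5-HT1B", "D2", "GABA_A/BZ", "H3"),
    ),
    "E:I_metabotropic": (
        ("5-HT2A", "5-HT4", "5-HT6", "D1", "M1", "mGluR5"),
        ("5-HT1A", "5-HT1B", "D2", "H3"),
    ),
    "E:I_ionotropic": (("α4β2", "NMDA"), ("GABA_A/BZ",)),
    "E:I_Glu/GABA": (("NMDA", "mGluR5"), ("GABA_A/BZ",)),
    "E:I_Glu/GABA(ion)": (("NMDA",), ("GABA_A/BZ",)),
    "R/Re_ACh": (("M1", "α4β2"), ("VAChT",)),
    "NT/NM": (
        ("GABA_A/BZ", "mGluR5", "NMDA"),
        ("5-HT1A", "5-HT1B", "5-HT2A", "5-HT4", "5-HT6", "α4β2", "D1", "D2", "M1", "H3"),
    ),
    "5-HT1A/5-HT1B": (("5-HT1A",), ("5-HT1B",)),
    "DAT/NET": (("DAT",), ("NET",)),
}


def receptor_ratio_maps(panel: ReceptorPanel | Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
    """All derived ratio maps, elementwise per region.

    On a constant all-ones panel the term counts force E:I = 8/5, R/Re_ACh =
    2/1 and NT/NM = 3/10 everywhere.
    """
    if not isinstance(panel, ReceptorPanel):
        panel = ReceptorPanel(dict(panel))
    out = {}
    for name, (num, den) in RATIO_FORMULAS.items():
        numerator = sum(panel[m] for m in num)
        denominator = sum(panel[m] for m in den)
        out[name] = numerator / denominator
    return out


def ratio_tau_association(
    maps: Mapping[str, np.ndarray],
    tau_map: np.ndarray,
    region_labels: Sequence[str],
    braak_assignment: Mapping[str, str],
) -> pd.DataFrame:
    """Correlate marker/ratio maps with a tau map and profile them by stage.

    Returns one row per map with the Pearson r against the tau map (missing
    for constant maps), the per-Braak-stage means, and the sort key
    ``stage VI mean - stage I mean`` (magnitude of change along the staging
    axis); rows are sorted by that key.
    """
    tau_map = np.asarray(tau_map, float)
    stages = ("I", "II", "III", "IV", "V", "VI")
    stage_members = {
        s: [i for i, lbl in enumerate(region_labels)
            if braak_assignment.get(lbl, "unassigned") == s]
        for s in stages
    }
    rows = []
    for name, values in maps.items():
        values = np.asarray(values, float)
        if values.std() == 0 or tau_map.std() == 0:
            r = np.nan
        else:
            r = float(pearsonr(values, tau_map).statistic)
        stage_means = {
            f"stage_{s}": (float(values[idx].mean()) if idx else np.nan)
            for s, idx in stage_members.items()
        }
        delta = stage_means["stage_VI"] - stage_means["stage_I"]
        rows.append(dict(map=name, r=r, **stage_means, stage_delta=delta))
    return pd.DataFrame(rows).sort_values("stage_delta", ascending=False).reset_index(drop=True)
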