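"""CSV / text readers and writers for the package's external formats.

Titration CSV: a header row with one ``total_<component>`` column per
component plus a ``signal`` column.  Anisotropy CSV: ``protein_dimer_M``
and ``anisotropy`` (or ``bound``/``free`` for gel-shift lanes).  SAXS
profiles use the standard 3-column q/I/sigma text format (see
:func:`metallosense.saxs.load_dat`).  All concentrations are molar unless
``micromolar=True`` is passed explicitly.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .dnabinding import BindingIsotherm
from .equilibria import TitrationExperiment

__all__ = [
    "read_titration_csv",
    "write_titration_csv",
    "read_isotherm_csv",
    "write_json_report",
]


def read_titration_csv(
    path,
    titrant: str,
    observable: dict[str, float] | None = None,
    *,
    micromolar: bool = False,
    label: str = "",
) -> TitrationExperiment:
    df = pd.read_csv(path)
    scale = 1e-6 if micromolar else 1.0
    totals = {
        c[len("total_"):]: df[c].to_numpy() * scale
        for c in df.columns
        if c.startswith("total_")
    }
    if "signal" not in df.columns:
        raise ValueError("titration CSV requires a 'signal' column")
    return TitrationExperiment(
        totals=totals,
        signal=df["signal"].to_numpy(),
        titrant=titrant,
        observable=observable or {},
        label=label or str(path),
    )


def write_titration_csv(path, experiment: TitrationExperiment) -> None:
    cols = {f"total_{k}": v for k, v in experiment.totals.items()}
    cols["signal"] = experiment.signal
    pd.DataFrame(cols).to_csv(path, index=False)


def read_isotherm_csv(
    path, dna_total: float, *, metallostate: str = "apo"
) -> BindingIsotherm:
    df = pd.read_csv(path)
    if "anisotropy" in df.columns:
        return BindingIsotherm(
            protein_dimer=df["protein_dimer_M"].to_numpy(),
            dna_total=dna_total,
            anisotropy=df["anisotropy"].to_numpy(),
            metallostate=metallostate,
        )
    raise ValueError("isotherm CSV requires an 'anisotropy' column")


def write_json_report(path, payload: dict) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_default)
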