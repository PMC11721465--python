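"""Sequential (competition) binding quantification.

The second-ligand binding magnitude is the Association-2 response gain —
response at the end of Association 2 minus response at its beginning — and
competition is summarised as the percent decrease of that gain relative to
the ligand-2-alone arm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bli import Sensorgram
from .errors import BlimapError, DesignMismatchError


@dataclass(frozen=True)
class CompetitionResult:
    ligand1: str
    ligand2: str
    conc1: float  # M (competitor; 0 in the alone arm by construction)
    conc2: float  # M
    gain_alone: float  # nm
    gain_competed: float  # nm
    percent_decrease: float  # %, negative = enhancement; NaN when undefined
    undefined_baseline: bool = False


def association2_gain(sensorgram: Sensorgram, robust: bool = True, step: str = "assoc2") -> float:
    """Association-2 gain: last-sample response minus first-sample response.

    With ``robust`` (default), each endpoint is the median of its nearest
    three samples, guarding against single-sample noise spikes.
    """
    st = sensorgram.step(step)
    if st.time.size == 0:
        raise BlimapError(f"step {step!r} is empty")
    if robust and st.time.size >= 3:
        first = float(np.median(st.response[:3]))
        last = float(np.median(st.response[-3:]))
    else:
        first = float(st.response[0])
        last = float(st.response[-1])
    return last - first


def percent_decrease(gain_alone: float, gain_competed: float) -> float:
    """100·(gain_alone − gain_competed)/gain_alone; NaN when the baseline
    gain is not positive (flagged by callers)."""
    if gain_alone <= 0:
        return float("nan")
    return 100.0 * (gain_alone - gain_competed) / gain_alone


def run_competition_pair(
    alone: Sensorgram,
    competed: Sensorgram,
    ligand1: str = "",
    conc1: float = 0.0,
    robust: bool = True,
) -> CompetitionResult:
    """Pair the no-competitor and competitor arms of one experiment.

    Both arms must probe the same second ligand at the same concentration
    (checked on the trace metadata).
    """
    if alone.analyte != competed.analyte:
        raise DesignMismatchError(
            f"second-ligand identity differs: {alone.analyte!r} vs {competed.analyte!r}"
        )
    if not np.isclose(alone.concentration, competed.concentration, rtol=1e-9, atol=0.0):
        raise DesignMismatchError(
            f"second-ligand concentration differs: {alone.concentration} vs "
            f"{competed.concentration}"
        )
    g_alone = association2_gain(alone, robust=robust)
    g_comp = association2_gain(competed, robust=robust)
    pct = percent_decrease(g_alone, g_comp)
    return CompetitionResult(
        ligand1=ligand1,
        ligand2=alone.analyte,
        conc1=conc1,
        conc2=alone.concentration,
        gain_alone=g_alone,
        gain_competed=g_comp,
        percent_decrease=pct,
        undefined_baseline=not g_alone > 0,
    )


def results_to_frame(results: list[CompetitionResult]) -> pd.DataFrame:
    """Tabulate competition results (percent decrease reported to 1 decimal)."""
    return pd.DataFrame(
        {
            "ligand1": [r.ligand1 for r in results],
            "conc1_M": [r.conc1 for r in results],
            "ligand2": [r.ligand2 for r in results],
            "conc2_M": [r.conc2 for r in results],
            "gain_alone_nm": [r.gain_alone for r in results],
            "gain_competed_nm": [r.gain_competed for r in results],
            "percent_decrease": [round(r.percent_decrease, 1) for r in results],
        }
    )
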