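"""Phenotypic response to multi-generation truncation selection.

Selected replicate lines are expressed as deviations from the mean of the
contemporaneous control lines (one control early on, two after the second
is split off), and the response is summarized by an ordinary
least-squares regression of deviation on generation number, per replicate
and for the replicate average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class Trajectory:
    """Deviation series of selected lines from contemporaneous controls.

    ``deviations`` is (replicate x generation); ``average`` the
    arithmetic mean over replicates per generation; ``control_mean`` the
    per-generation control average the deviations were taken against.
    """

    generations: np.ndarray
    deviations: pd.DataFrame
    average: pd.Series
    control_mean: pd.Series


def _wide(df: pd.DataFrame) -> pd.DataFrame:
    """Long (generation, population_id, proportion) -> wide per population."""
    if "proportion" not in df.columns:
        df = df.assign(proportion=df["n_mated"] / df["n_assayed"])
    return df.pivot_table(index="population_id", columns="generation", values="proportion")


def deviation_trajectory(selected: pd.DataFrame, control: pd.DataFrame) -> Trajectory:
    """Deviation of each selected replicate from the contemporaneous
    control mean, per generation.

    Inputs are long-form tables with columns ``generation``,
    ``population_id`` and either ``proportion`` or ``n_assayed`` +
    ``n_mated``.  The control mean at each generation averages over
    however many control populations have data there.
    """
    sel = _wide(selected)
    ctl = _wide(control)
    gens = sel.columns.to_numpy()
    if not set(gens) <= set(ctl.columns):
        missing = sorted(set(gens) - set(ctl.columns))
        raise ValueError(f"control series missing generations {missing}")
    ctl_mean = ctl[gens].mean(axis=0)
    dev = sel - ctl_mean
    avg = dev.mean(axis=0)
    return Trajectory(
        generations=np.asarray(gens),
        deviations=dev,
        average=avg,
        control_mean=ctl_mean,
    )


def response_regression(traj: Trajectory) -> pd.DataFrame:
    """OLS of deviation on generation, per replicate and for the average.

    Returns a table with ``series`` ('average' or the replicate id),
    slope ``b``, intercept, and the two-sided t-test p-value on the slope.
    """
    if len(traj.generations) < 3:
        raise ValueError("regression needs at least 3 generations")
    if np.ptp(traj.generations) == 0:
        raise ValueError("degenerate generation grid")
    rows = []
    series = {rid: traj.deviations.loc[rid] for rid in traj.deviations.index}
    series["average"] = traj.average
    for name, s in series.items():
        x = np.asarray(s.index, dtype=float)
        yv = s.to_numpy(dtype=float)
        res = stats.linregress(x, yv)
        rows.append(
            {
                "series": name,
                "b": res.slope,
                "intercept": res.intercept,
                "p_value": res.pvalue,
                "r": res.rvalue,
            }
        )
    return pd.DataFrame(rows)
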