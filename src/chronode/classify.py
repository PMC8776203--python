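"""Target-gene taxonomy: timing, direction and fold-change profile, plus Venn overlaps.

Timing: a target significant at 4 or 8 h is *primary* (responding before the
secondary transcription-factor wave can act); one significant only at 24/48 h
is *secondary*.  Direction is read off the per-time log2FC vector using a
fold-change threshold; both signs above threshold give *mixed*.  The profile
says whether the fold change is *persistent* through 48 h, *transient*
(gone by 48 h) or *discontinuous* (dips below threshold at an intermediate
time point but is significant again later).
"""

from __future__ import annotations

import itertools
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

TIMINGS = ("primary", "secondary")
DIRECTIONS = ("up", "down", "mixed")
PROFILES = ("persistent", "transient", "discontinuous")


def classify_timing(significant_times: Iterable[int]) -> str:
    """Primary iff significant at 4 or 8 h."""
    times = set(significant_times)
    if not times:
        raise ValueError("a target gene must be significant at >= 1 time point")
    return "primary" if times & {4, 8} else "secondary"


def classify_direction(
    log2fc: Mapping[int, float],
    fc_threshold: float = 1.5,
    significant_times: Iterable[int] | None = None,
) -> str:
    """Direction over all time points whose |FC| exceeds the threshold.

    All positive -> up, all negative -> down, both -> mixed.  When no time
    point exceeds the threshold, the sign at the significant time points
    decides (fallback; avoids an undefined class).
    """
    if fc_threshold <= 1.0:
        raise ValueError("fc_threshold must be > 1")
    thr = np.log2(fc_threshold)
    signs = {np.sign(v) for t, v in log2fc.items() if abs(v) > thr and v != 0}
    if not signs:
        if significant_times is None:
            raise ValueError(
                "no |FC| exceeds the threshold and no significant times were given"
            )
        signs = {np.sign(log2fc[t]) for t in significant_times if log2fc[t] != 0}
        if not signs:
            return "mixed"
    if signs == {1.0}:
        return "up"
    if signs == {-1.0}:
        return "down"
    return "mixed"


def classify_profile(
    significant_times: Iterable[int],
    log2fc: Mapping[int, float],
    fc_threshold: float = 1.5,
) -> str:
    """Persistent / transient / discontinuous, with precedence discontinuous > transient.

    * discontinuous: significant at some time point *after* an intermediate
      time point at which |FC| fell to or below the threshold;
    * persistent: |FC| stays above the threshold at every time point from the
      first significance through 48 h;
    * transient: not significant at the last time point and |FC| below the
      threshold there.

    A residual gene (threshold-crossing at 48 h without late significance
    after a dip) is called transient when not significant at 48 h, else
    persistent.
    """
    sig = set(significant_times)
    if not sig:
        raise ValueError("a target gene must be significant at >= 1 time point")
    times = sorted(log2fc)
    thr = np.log2(fc_threshold)
    last = times[-1]
    t_first = min(sig)
    span = [t for t in times if t >= t_first]
    # intermediate dip followed by renewed significance
    for t_mid, t_late in itertools.combinations(span, 2):
        if t_mid > t_first and t_late in sig and abs(log2fc[t_mid]) <= thr:
            return "discontinuous"
    if all(abs(log2fc[t]) > thr for t in span):
        return "persistent"
    if last not in sig and abs(log2fc[last]) <= thr:
        return "transient"
    return "persistent" if last in sig else "transient"


def classify_targets(
    significant_times: Mapping[str, set[int]],
    log2fc_matrix: pd.DataFrame,
    fc_threshold: float = 1.5,
) -> pd.DataFrame:
    """Classify every target gene on the three axes.

    Parameters
    ----------
    significant_times
        gene -> set of significant time points (from
        :meth:`~chronode.detest.TreatDEResults.significant_times`).
    log2fc_matrix
        genes x time points log2FC (from
        :meth:`~chronode.detest.TreatDEResults.log2fc_matrix`).
    """
    rows = []
    for gene in sorted(significant_times):
        times = significant_times[gene]
        fc = log2fc_matrix.loc[gene].to_dict()
        fc = {int(t): float(v) for t, v in fc.items()}
        rows.append(
            {
                "gene": gene,
                "significant_times": ",".join(str(t) for t in sorted(times)),
                "timing": classify_timing(times),
                "direction": classify_direction(fc, fc_threshold, significant_times=times),
                "profile": classify_profile(times, fc, fc_threshold),
                **{f"log2FC_{t}": fc[t] for t in sorted(fc)},
            }
        )
    columns = ["gene", "significant_times", "timing", "direction", "profile"] + [
        f"log2FC_{t}" for t in sorted(int(t) for t in log2fc_matrix.columns)
    ]
    return pd.DataFrame(rows, columns=columns).set_index("gene")


def venn_counts(sets: Mapping[int, set[str]]) -> pd.DataFrame:
    """Exclusive region counts for all non-empty intersections of the given sets.

    Returns one row per non-empty membership pattern; ``count`` sums to the
    size of the union over all rows.
    """
    keys = sorted(sets)
    union = sorted(set().union(*sets.values())) if sets else []
    patterns: dict[tuple[bool, ...], int] = {}
    for g in union:
        pat = tuple(g in sets[k] for k in keys)
        patterns[pat] = patterns.get(pat, 0) + 1
    rows = []
    for r in range(len(keys), 0, -1):
        for combo in itertools.combinations(keys, r):
            pat = tuple(k in combo for k in keys)
            rows.append(
                {
                    "region": "&".join(str(k) for k in combo),
                    "count": patterns.get(pat, 0),
                }
            )
    out = pd.DataFrame(rows, columns=["region", "count"])
    assert out["count"].sum() == len(union), "Venn regions must partition the union"
    return out
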