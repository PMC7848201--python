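"""Reference-pattern clustering.

Each unit (gene or LSV junction) is summarised as its mean profile over the
ordered physiological states, correlated against a small set of named
reference templates, and assigned to the best-correlating template when the
Pearson r reaches the configured minimum; otherwise it falls into the
``Unassigned`` cluster.

Templates are data, not code: the default set below can be replaced by any
table of name -> per-state relative levels (see :func:`load_templates`).
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np
import pandas as pd

from .config import STATES, ClusterConfig

__all__ = [
    "DEFAULT_TEMPLATES",
    "load_templates",
    "save_templates",
    "state_means",
    "correlate_templates",
    "assign_clusters",
]

#: Canonical template shapes over (SA, IBA, Ent, LT, Ar, SpD).  EH/EM/EL
#: encode the relative level during entrance into torpor (high/medium/low).
DEFAULT_TEMPLATES: "OrderedDict[str, tuple[float, ...]]" = OrderedDict(
    [
        ("Winter_high", (0, 1, 1, 1, 1, 0)),
        ("Winter_low", (1, 0, 0, 0, 0, 1)),
        ("IBA_high", (0, 1, 0, 0, 0, 0)),
        ("IBA_low", (1, 0, 1, 1, 1, 1)),
        ("Cold_high_EH", (0, 0, 1, 1, 1, 0)),
        ("Cold_high_EM", (0, 0, 0.5, 1, 1, 0)),
        ("Cold_high_EL", (0, 0, 0, 1, 1, 0)),
        ("Cold_low_EH", (1, 1, 1, 0, 0, 1)),
        ("Cold_low_EM", (1, 1, 0.5, 0, 0, 1)),
        ("Cold_low_EL", (1, 1, 0, 0, 0, 1)),
    ]
)


def load_templates(path) -> "OrderedDict[str, tuple[float, ...]]":
    """Read templates from a TSV with a ``name`` column followed by one
    column per state (header row gives the state order)."""
    df = pd.read_csv(path, sep="\t")
    out: OrderedDict[str, tuple[float, ...]] = OrderedDict()
    for _, row in df.iterrows():
        out[str(row.iloc[0])] = tuple(float(v) for v in row.iloc[1:])
    return out


def save_templates(templates, path, states: tuple[str, ...] = STATES) -> None:
    rows = [{"name": name, **dict(zip(states, vec))} for name, vec in templates.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def state_means(
    expr: pd.DataFrame, design: pd.DataFrame, states: tuple[str, ...] = STATES
) -> pd.DataFrame:
    """Arithmetic mean of transformed values per state, canonical order.

    ``expr`` is units x samples; ``design`` must carry ``sample_id`` and
    ``state`` columns covering the expression columns.
    """
    state_of = dict(zip(design["sample_id"], design["state"]))
    missing = [s for s in expr.columns if s not in state_of]
    if missing:
        raise ValueError(f"samples missing from design: {missing[:5]}")
    cols = {}
    for state in states:
        samples = [s for s in expr.columns if state_of[s] == state]
        if not samples:
            raise ValueError(f"state {state!r} has no samples")
        cols[state] = expr[samples].mean(axis=1)
    return pd.DataFrame(cols, index=expr.index)


def _template_matrix(templates) -> tuple[list[str], np.ndarray]:
    names = list(templates)
    if not names:
        raise ValueError("empty template list")
    mat = np.asarray([templates[n] for n in names], dtype=float)
    if np.any(mat.std(axis=1) == 0):
        flat = [n for n, v in zip(names, mat) if np.std(v) == 0]
        raise ValueError(f"constant template(s): {flat}")
    return names, mat


def correlate_templates(means: pd.DataFrame, templates) -> pd.DataFrame:
    """Pearson r of every unit profile against every template.

    Zero-variance (flat) profiles yield NaN for every template: Pearson r
    is undefined there and such units are never assigned.
    """
    names, tmat = _template_matrix(templates)
    x = means.to_numpy(dtype=float)
    if x.shape[1] < 3:
        raise ValueError("need at least 3 states to correlate")
    if x.shape[1] != tmat.shape[1]:
        raise ValueError("template length does not match number of states")
    xc = x - x.mean(axis=1, keepdims=True)
    xsd = xc.std(axis=1)
    tc = tmat - tmat.mean(axis=1, keepdims=True)
    tsd = tc.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ tc.T) / (x.shape[1] * np.outer(xsd, tsd))
    r[xsd == 0, :] = np.nan
    return pd.DataFrame(r, index=means.index, columns=names)


def assign_clusters(
    means: pd.DataFrame, templates, config: ClusterConfig | None = None
) -> pd.DataFrame:
    """Assign each unit to its best-correlating template at r >= r_min.

    Returns a frame indexed like ``means`` with columns ``cluster``,
    ``r_best`` and ``r_runner_up``.  Exact ties are broken by the declared
    template order (first wins) and marked in a ``tie`` column.
    """
    config = config or ClusterConfig()
    config.validate()
    r = correlate_templates(means, templates)
    rv = r.to_numpy()
    names = np.asarray(r.columns)

    # nan-safe argmax honouring template order on exact ties
    filled = np.where(np.isnan(rv), -np.inf, rv)
    best_idx = filled.argmax(axis=1)
    r_best = filled[np.arange(len(filled)), best_idx]
    tie = (filled == r_best[:, None]).sum(axis=1) > 1
    second = np.partition(filled, -2, axis=1)[:, -2] if filled.shape[1] > 1 else np.full(len(filled), -np.inf)

    cluster = np.where(
        (r_best >= config.r_min) & np.isfinite(r_best),
        names[best_idx],
        config.unassigned_label,
    )
    out = pd.DataFrame(
        {
            "cluster": cluster,
            "r_best": np.where(np.isfinite(r_best), r_best, np.nan),
            "r_runner_up": np.where(np.isfinite(second), second, np.nan),
            "tie": tie & np.isfinite(r_best),
        },
        index=means.index,
    )
    return out
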