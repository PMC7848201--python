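"""Local-splicing-variation PSI/dPSI estimation and classification.

Per state, junction counts are pooled across replicates and a Dirichlet
posterior (Jeffreys prior by default) gives the per-junction PSI.  dPSI
between two states is the difference of independent posterior draws,
summarised by its mean and the one-sided probabilities of exceeding the
configured delta; an LSV is significant when any junction reaches the
probability threshold in any pairwise state comparison.  Profiles relative
to the reference (summer-active) state orient patterns to the
summer-dominant junction and, separately, to the retained intron when one
is present.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import STATES, ClusterConfig, SpliceConfig
from .clustering import assign_clusters

__all__ = [
    "LsvRecord",
    "PsiEstimate",
    "lsv_records_from_table",
    "estimate_psi",
    "dominant_junction",
    "dpsi_test",
    "significant_lsvs",
    "cluster_dpsi_patterns",
    "classify_intron_retention",
    "select_control_introns",
]

logger = logging.getLogger(__name__)


@dataclass
class LsvRecord:
    """One LSV: junction metadata plus a junction x sample count table."""

    lsv_id: str
    gene_id: str
    junction_ids: list[str]
    is_retained_intron: np.ndarray  # bool per junction
    counts: pd.DataFrame  # junctions x samples
    coords: pd.DataFrame | None = None  # per junction: chrom, strand, start, end

    def __post_init__(self):
        if len(self.junction_ids) < 2:
            raise ValueError(f"{self.lsv_id}: an LSV needs >= 2 junctions")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError(f"{self.lsv_id}: counts must be >= 0")


@dataclass
class PsiEstimate:
    """Posterior PSI summaries for one LSV."""

    lsv_id: str
    gene_id: str
    junction_ids: list[str]
    is_retained_intron: np.ndarray
    alphas: pd.DataFrame  # state x junction Dirichlet parameters
    psi_mean: pd.DataFrame  # state x junction posterior means
    psi_low: pd.DataFrame
    psi_high: pd.DataFrame
    informative: dict[str, bool]
    coords: pd.DataFrame | None = None
    # (state_a, state_b) -> per-junction frame [e_dpsi, p_ge, p_le]
    dpsi: dict = field(default_factory=dict)


def lsv_records_from_table(table: pd.DataFrame) -> list[LsvRecord]:
    """Build LSV records from the long-format junction-count table
    (columns: lsv_id, gene_id, junction_id, is_retained_intron, sample,
    count, and optionally chrom/strand/start/end)."""
    required = {"lsv_id", "gene_id", "junction_id", "is_retained_intron", "sample", "count"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"LSV table missing columns: {sorted(missing)}")
    has_coords = {"chrom", "strand", "start", "end"} <= set(table.columns)
    records = []
    for lsv_id, grp in table.groupby("lsv_id", sort=True):
        mat = grp.pivot_table(
            index="junction_id", columns="sample", values="count", aggfunc="sum"
        ).fillna(0)
        meta = grp.drop_duplicates("junction_id").set_index("junction_id")
        mat = mat.loc[sorted(mat.index)]
        coords = None
        if has_coords:
            coords = meta.loc[mat.index, ["chrom", "strand", "start", "end"]]
        records.append(
            LsvRecord(
                lsv_id=str(lsv_id),
                gene_id=str(grp["gene_id"].iloc[0]),
                junction_ids=list(mat.index),
                is_retained_intron=meta.loc[mat.index, "is_retained_intron"]
                .astype(bool)
                .to_numpy(),
                counts=mat,
                coords=coords,
            )
        )
    return records


def estimate_psi(
    lsv: LsvRecord,
    design: pd.DataFrame,
    config: SpliceConfig | None = None,
    states: tuple[str, ...] = STATES,
) -> PsiEstimate:
    """Pool replicate counts per state and form the Dirichlet posterior.

    A state whose pooled counts are all zero is flagged uninformative and
    is excluded from downstream tests.
    """
    config = config or SpliceConfig()
    config.validate()
    state_of = dict(zip(design["sample_id"], design["state"]))
    pooled = {}
    informative = {}
    for state in states:
        samples = [s for s in lsv.counts.columns if state_of.get(s) == state]
        tot = (
            lsv.counts[samples].sum(axis=1).to_numpy(dtype=float)
            if samples
            else np.zeros(len(lsv.junction_ids))
        )
        pooled[state] = tot
        informative[state] = bool(tot.sum() > 0)
    alphas = pd.DataFrame(
        {s: pooled[s] + config.prior_pseudocount for s in states},
        index=lsv.junction_ids,
    ).T
    mean = alphas.div(alphas.sum(axis=1), axis=0)
    # credible interval from the marginal Beta of each component
    a = alphas.to_numpy()
    tot = a.sum(axis=1, keepdims=True)
    low = stats.beta.ppf(0.025, a, tot - a)
    high = stats.beta.ppf(0.975, a, tot - a)
    return PsiEstimate(
        lsv_id=lsv.lsv_id,
        gene_id=lsv.gene_id,
        junction_ids=lsv.junction_ids,
        is_retained_intron=lsv.is_retained_intron,
        alphas=alphas,
        psi_mean=mean,
        psi_low=pd.DataFrame(low, index=alphas.index, columns=alphas.columns),
        psi_high=pd.DataFrame(high, index=alphas.index, columns=alphas.columns),
        informative=informative,
        coords=lsv.coords,
    )


def dominant_junction(psi: PsiEstimate, config: SpliceConfig | None = None) -> str:
    """The junction with the highest posterior-mean PSI in the reference
    state; exact ties go to the lexicographically smallest junction id."""
    config = config or SpliceConfig()
    ref = config.reference_state
    if not psi.informative.get(ref, False):
        raise ValueError(f"{psi.lsv_id}: reference state {ref!r} is uninformative")
    row = psi.psi_mean.loc[ref]
    best = row.max()
    winners = sorted(row.index[row == best])
    if len(winners) > 1:
        logger.warning("%s: PSI tie in %s among %s; taking %s", psi.lsv_id, ref, winners, winners[0])
    return winners[0]


def _pair_rng(config: SpliceConfig, lsv_id: str, a: str, b: str) -> np.random.Generator:
    return np.random.default_rng(
        [config.seed, zlib.crc32(lsv_id.encode()), zlib.crc32(a.encode()), zlib.crc32(b.encode())]
    )


def dpsi_test(
    psi: PsiEstimate,
    state_a: str,
    state_b: str,
    config: SpliceConfig | None = None,
    prob_threshold: float | None = None,
) -> tuple[bool, pd.DataFrame]:
    """Monte-Carlo dPSI (state_b minus state_a) per junction.

    Returns (significant, frame) where the frame has per-junction
    ``e_dpsi`` (closed-form posterior-mean difference), ``p_ge`` and
    ``p_le`` (one-sided exceedance probabilities at the configured delta);
    the LSV is significant when any junction's larger one-sided
    probability reaches the threshold.
    """
    config = config or SpliceConfig()
    config.validate()
    threshold = config.prob_threshold if prob_threshold is None else prob_threshold
    for st in (state_a, state_b):
        if not psi.informative.get(st, False):
            raise ValueError(f"{psi.lsv_id}: state {st!r} is uninformative")
    if (state_a, state_b) not in psi.dpsi:
        rng = _pair_rng(config, psi.lsv_id, state_a, state_b)
        draws_a = rng.dirichlet(psi.alphas.loc[state_a].to_numpy(), config.mc_samples)
        draws_b = rng.dirichlet(psi.alphas.loc[state_b].to_numpy(), config.mc_samples)
        d = draws_b - draws_a
        frame = pd.DataFrame(
            {
                "e_dpsi": (psi.psi_mean.loc[state_b] - psi.psi_mean.loc[state_a]).to_numpy(),
                "p_ge": (d >= config.delta).mean(axis=0),
                "p_le": (d <= -config.delta).mean(axis=0),
            },
            index=psi.junction_ids,
        )
        psi.dpsi[(state_a, state_b)] = frame
    frame = psi.dpsi.get((state_a, state_b))
    sig = bool(frame[["p_ge", "p_le"]].to_numpy().max() >= threshold)
    return sig, frame


def significant_lsvs(
    estimates: list[PsiEstimate],
    config: SpliceConfig | None = None,
    states: tuple[str, ...] = STATES,
    prob_threshold: float | None = None,
    state_pairs: list[tuple[str, str]] | None = None,
) -> set[str]:
    """IDs of LSVs significant in any pairwise state comparison."""
    config = config or SpliceConfig()
    if state_pairs is None:
        state_pairs = [
            (states[i], states[j])
            for i in range(len(states))
            for j in range(i + 1, len(states))
        ]
    out = set()
    for est in estimates:
        for a, b in state_pairs:
            if not (est.informative.get(a) and est.informative.get(b)):
                continue
            sig, _ = dpsi_test(est, a, b, config, prob_threshold=prob_threshold)
            if sig:
                out.add(est.lsv_id)
                break
    return out


def cluster_dpsi_patterns(
    estimates: list[PsiEstimate],
    templates,
    config: SpliceConfig | None = None,
    cluster_config: ClusterConfig | None = None,
    states: tuple[str, ...] = STATES,
) -> pd.DataFrame:
    """Assign reference-pattern clusters to per-LSV dPSI-vs-reference
    profiles.

    For each LSV two profiles may be built: the reference-dominant
    junction's, and (separately) the retained intron's when present.  The
    profile entry for the reference state is exactly 0 by construction.
    Units are labeled ``<lsv_id>:<junction_id>`` with a ``kind`` column of
    ``dominant`` or ``retained_intron``.
    """
    config = config or SpliceConfig()
    ref = config.reference_state
    rows = {}
    kinds = {}
    for est in estimates:
        if not est.informative.get(ref, False):
            raise ValueError(f"{est.lsv_id}: missing reference-state estimate")
        targets = [("dominant", dominant_junction(est, config))]
        if est.is_retained_intron.any():
            ri = est.junction_ids[int(np.argmax(est.is_retained_intron))]
            if ri != targets[0][1]:
                targets.append(("retained_intron", ri))
            else:
                kinds_label = "dominant_retained_intron"
                targets = [(kinds_label, ri)]
        for kind, j in targets:
            profile = (est.psi_mean[j] - est.psi_mean.loc[ref, j]).reindex(list(states))
            rows[f"{est.lsv_id}:{j}"] = profile.to_numpy()
            kinds[f"{est.lsv_id}:{j}"] = kind
    if not rows:
        return pd.DataFrame(columns=["cluster", "r_best", "r_runner_up", "tie", "kind"])
    means = pd.DataFrame.from_dict(rows, orient="index", columns=list(states))
    out = assign_clusters(means, templates, cluster_config or ClusterConfig())
    out["kind"] = pd.Series(kinds)
    return out


def classify_intron_retention(
    psi: PsiEstimate, config: SpliceConfig | None = None
) -> str:
    """``retained-default`` when the retained-intron junction has the
    maximum reference-state PSI (ties included, logged), else
    ``excised-default``."""
    config = config or SpliceConfig()
    if not psi.is_retained_intron.any():
        raise ValueError(f"{psi.lsv_id}: no retained-intron junction")
    ref = config.reference_state
    row = psi.psi_mean.loc[ref]
    ri = psi.junction_ids[int(np.argmax(psi.is_retained_intron))]
    best = row.max()
    if row[ri] == best:
        if (row == best).sum() > 1:
            logger.warning("%s: retained-intron PSI tie in %s; calling retained-default", psi.lsv_id, ref)
        return "retained-default"
    return "excised-default"


def _temperature_dependent(est: PsiEstimate, config: SpliceConfig) -> bool:
    """Significant at the relaxed probability gate in any warm-vs-cold pair."""
    for a in config.warm_states:
        for b in config.cold_states:
            if not (est.informative.get(a) and est.informative.get(b)):
                continue
            sig, _ = dpsi_test(est, a, b, config, prob_threshold=config.ir_prob_threshold)
            if sig:
                return True
    return False


def select_control_introns(
    estimates: list[PsiEstimate],
    config: SpliceConfig | None = None,
) -> pd.DataFrame:
    """Non-temperature-dependent retained introns that do not genomically
    overlap any temperature-dependent one, as a 6-column BED-like frame.

    Introns without coordinates are skipped (logged).  The emitted
    intervals are the retained-intron spans; their ends are the flanking
    splice-site coordinates for external strength scoring.
    """
    config = config or SpliceConfig()
    retained = []
    for est in estimates:
        if not est.is_retained_intron.any():
            continue
        ri = est.junction_ids[int(np.argmax(est.is_retained_intron))]
        if est.coords is None or ri not in est.coords.index:
            logger.warning("%s: retained intron lacks coordinates; skipped", est.lsv_id)
            continue
        c = est.coords.loc[ri]
        retained.append(
            {
                "lsv_id": est.lsv_id,
                "junction_id": ri,
                "chrom": c["chrom"],
                "start": int(c["start"]),
                "end": int(c["end"]),
                "strand": c["strand"],
                "significant": _temperature_dependent(est, config),
            }
        )
    sig = [r for r in retained if r["significant"]]
    controls = []
    for r in retained:
        if r["significant"]:
            continue
        overlaps = any(
            r["chrom"] == s["chrom"] and r["start"] < s["end"] and s["start"] < r["end"]
            for s in sig
        )
        if overlaps:
            continue
        controls.append(
            {
                "chrom": r["chrom"],
                "start": r["start"],
                "end": r["end"],
                "name": f"{r['lsv_id']}:{r['junction_id']}",
                "score": 0,
                "strand": r["strand"],
            }
        )
    return pd.DataFrame(
        controls, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
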