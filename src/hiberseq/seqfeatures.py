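"""Sequence features and set-enrichment statistics.

GC content, AU-rich-element (ARE) scoring of 3'UTRs, IUPAC motif scanning,
k-mer presence enrichment, cluster-by-feature Fisher tests, Wilcoxon
rank-sum comparisons, and GO-style over-representation against an explicit
background.  All sequences are handled in the DNA alphabet ("AUUUA" is
scored as "ATTTA").

The ARE score is an approximation of the published web tool: with P the
number of (possibly overlapping) pentamer occurrences and C the number of
consecutive occurrence pairs closer than pentamer length + cluster_gap, the
score is ``P + cluster_bonus * C``; 0 means "no ARE" and >= high_score_min
means "high ARE".
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import AREConfig

__all__ = [
    "gc_content",
    "find_occurrences",
    "are_score",
    "are_class",
    "motif_scan",
    "kmer_enrichment",
    "cluster_feature_fisher",
    "wilcoxon_compare",
    "read_gmt",
    "go_enrichment",
]

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[GC]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}

_VALID_SEQ = re.compile(r"^[ACGTNacgtn]*$")


def gc_content(seq: str) -> float:
    """(G + C) / (A + C + G + T), case-insensitive; N bases are excluded
    from the denominator.  NaN when no unambiguous base remains."""
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        return float("nan")
    return gc / (gc + at)


def find_occurrences(seq: str, pattern: str) -> list[int]:
    """Start positions of all (possibly overlapping) exact occurrences."""
    s = seq.upper()
    p = pattern.upper()
    out = []
    i = s.find(p)
    while i != -1:
        out.append(i)
        i = s.find(p, i + 1)
    return out


def are_score(utr3: str, config: AREConfig | None = None) -> float | None:
    """ARE score of a 3'UTR, or None when the sequence is shorter than the
    minimum length (excluded, not scored)."""
    config = config or AREConfig()
    config.validate()
    if not _VALID_SEQ.match(utr3):
        bad = sorted(set(utr3.upper()) - set("ACGTN"))
        raise ValueError(f"non-ACGTN characters in sequence: {bad}")
    if len(utr3) < config.min_utr_len:
        return None
    starts = find_occurrences(utr3, config.pentamer)
    p = len(starts)
    max_gap = len(config.pentamer) + config.cluster_gap
    c = sum(
        1 for i in range(len(starts) - 1) if starts[i + 1] - starts[i] <= max_gap
    )
    return p + config.cluster_bonus * c


def are_class(score: float | None, config: AREConfig | None = None) -> str | None:
    """"no_ARE" at score 0, "high_ARE" at or above the high threshold,
    "mid_ARE" between, None for excluded sequences."""
    if score is None:
        return None
    config = config or AREConfig()
    if score == 0:
        return "no_ARE"
    if score >= config.high_score_min:
        return "high_ARE"
    return "mid_ARE"


def _iupac_regex(motif: str) -> re.Pattern:
    if not motif:
        raise ValueError("motif must be non-empty")
    try:
        body = "".join(_IUPAC[c] for c in motif.upper())
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code in motif: {exc.args[0]!r}") from None
    return re.compile(f"(?=({body}))")  # lookahead: overlapping matches


def motif_scan(sequences: dict[str, str], motif: str) -> pd.DataFrame:
    """Overlapping IUPAC-motif matches per sequence, with per-kb density."""
    pat = _iupac_regex(motif)
    rows = []
    for name, seq in sequences.items():
        n = len(pat.findall(seq.upper()))
        rows.append(
            {
                "sequence": name,
                "count": n,
                "length": len(seq),
                "per_kb": (n * 1000.0 / len(seq)) if seq else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("sequence")


def _fisher(table: np.ndarray) -> tuple[float, float]:
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return odds, p


def kmer_enrichment(
    foreground: dict[str, str], background: dict[str, str], k: int
) -> pd.DataFrame:
    """Sequence-level k-mer presence enrichment (Fisher exact, BH).

    The 2x2 per k-mer counts sequences containing / lacking the k-mer in
    each set; all k-mers present in either set are tested.
    """
    if not 1 <= k <= 12:
        raise ValueError("k must be in [1, 12]")
    if not foreground or not background:
        raise ValueError("both sequence sets must be non-empty")

    def presence(seqs: dict[str, str]) -> dict[str, int]:
        tally: dict[str, int] = {}
        for seq in seqs.values():
            s = seq.upper()
            seen = {s[i : i + k] for i in range(len(s) - k + 1)}
            for km in seen:
                if "N" not in km:
                    tally[km] = tally.get(km, 0) + 1
        return tally

    fg = presence(foreground)
    bg = presence(background)
    n_fg, n_bg = len(foreground), len(background)
    rows = []
    for km in sorted(set(fg) | set(bg)):
        a = fg.get(km, 0)
        b = n_fg - a
        c = bg.get(km, 0)
        d = n_bg - c
        odds, p = _fisher(np.array([[a, b], [c, d]]))
        rows.append(
            {"item": km, "fg_present": a, "fg_absent": b,
             "bg_present": c, "bg_absent": d, "odds_ratio": odds, "pvalue": p}
        )
    out = pd.DataFrame(rows).set_index("item")
    out["qvalue"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    return out


def cluster_feature_fisher(
    assignments: pd.Series,
    feature_classes: pd.Series,
    background: list[str],
) -> pd.DataFrame:
    """Per cluster x feature class Fisher test of in-cluster counts vs the
    rest of the background.

    ``assignments`` maps unit -> cluster, ``feature_classes`` unit ->
    class label.  Units outside ``background`` are ignored; empty clusters
    are skipped.
    """
    bg = [g for g in background if g in feature_classes.index]
    bg_set = set(bg)
    rows = []
    for cluster in sorted(assignments.dropna().unique()):
        members = [g for g in assignments.index[assignments == cluster] if g in bg_set]
        if not members:
            continue
        rest = bg_set - set(members)
        for cls in sorted(feature_classes.dropna().unique()):
            a = sum(feature_classes.get(g) == cls for g in members)
            b = len(members) - a
            c = sum(feature_classes.get(g) == cls for g in rest)
            d = len(rest) - c
            odds, p = _fisher(np.array([[a, b], [c, d]]))
            rows.append(
                {"cluster": cluster, "feature_class": cls,
                 "in_cluster_class": a, "in_cluster_other": b,
                 "background_class": c, "background_other": d,
                 "odds_ratio": odds, "pvalue": p}
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["qvalue"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    return out


def wilcoxon_compare(a, b) -> float:
    """Two-sided Mann-Whitney U p-value; exact when the smaller group has
    at most 8 values and no ties straddle the groups, tie-corrected normal
    approximation otherwise."""
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ties = len(set(a) & set(b)) > 0 or len(set(a.tolist() + b.tolist())) < a.size + b.size
    method = "exact" if (min(a.size, b.size) <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def read_gmt(path) -> dict[str, set[str]]:
    """Parse a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT rows need >= 3 columns")
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def go_enrichment(
    genes: set[str] | list[str],
    collections: dict[str, set[str]],
    background: set[str] | list[str],
) -> pd.DataFrame:
    """Per-term Fisher over-representation against an explicit background.

    All margins are restricted to the background; raises when the query
    set shares no genes with it.
    """
    bg = set(background)
    query = set(genes) & bg
    if not query:
        raise ValueError("gene set is disjoint from the background")
    rows = []
    for term, members in collections.items():
        term_bg = members & bg
        a = len(query & term_bg)
        b = len(query) - a
        c = len(term_bg) - a
        d = len(bg) - len(query) - c
        odds, p = _fisher(np.array([[a, b], [c, d]]))
        rows.append(
            {"item": term, "in_set_in_term": a, "in_set_not_term": b,
             "not_set_in_term": c, "not_set_not_term": d,
             "odds_ratio": odds, "pvalue": p}
        )
    out = pd.DataFrame(rows).set_index("item")
    if len(out):
        out["qvalue"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    return out
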