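"""Synthetic-data generators with known ground truth.

Every downstream stage of the pipeline can be exercised on the outputs of
this module: a sample design, negative-binomial count matrices whose
state-mean profiles follow the named cluster templates, LSV junction-count
tables with planted per-state PSI, a hand-constructible annotation-merge
fixture, and sequences with planted AU-rich pentamers / GC targets /
motifs.

All generators are deterministic given their seed; each draws from a
single, explicitly seeded RNG stream (no global state).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import JunctionEvidence, TranscriptModel
from .clustering import DEFAULT_TEMPLATES
from .config import ConfigurationError, SimulationConfig

__all__ = [
    "gen_design",
    "gen_counts",
    "LsvTemplate",
    "gen_lsv_counts",
    "gen_annotation_fixture",
    "PlantSpec",
    "gen_sequences",
    "write_counts",
    "read_counts",
    "write_design",
    "read_design",
    "write_lsv_table",
    "read_lsv_table",
    "write_fasta",
    "read_fasta",
]

_SEXES = ("F", "M")


def _rng(seed: int, tag: str) -> np.random.Generator:
    # distinct, reproducible stream per generator
    return np.random.default_rng([seed, zlib.crc32(tag.encode())])


def gen_design(config: SimulationConfig) -> pd.DataFrame:
    """Sample design table: one row per sample with state, sex and region.

    Sexes alternate within each state (near-balanced); which sex leads is
    drawn deterministically from the seed.
    """
    config.validate()
    rng = _rng(config.seed, "design")
    rows = []
    for state in config.states:
        lead = int(rng.integers(0, 2))
        for i in range(config.n_per_state):
            rows.append(
                {
                    "sample_id": f"{state}_{i + 1}",
                    "state": state,
                    "sex": _SEXES[(lead + i) % 2],
                    "region": config.region,
                }
            )
    return pd.DataFrame(rows)


def _template_assignments(config: SimulationConfig) -> list[str]:
    labels: list[str] = []
    for name, frac in config.cluster_fractions.items():
        if name not in DEFAULT_TEMPLATES and name not in getattr(config, "_templates", {}):
            raise ConfigurationError(f"unknown template name in cluster_fractions: {name!r}")
        labels.extend([name] * int(round(frac * config.n_genes)))
    if len(labels) > config.n_genes:
        labels = labels[: config.n_genes]
    labels.extend(["null"] * (config.n_genes - len(labels)))
    return labels


def gen_counts(
    design: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial gene x sample counts plus a truth table.

    Gene i generated from template k has state log2-means
    ``baseline + amplitude * template_k(state) (+ sex offset)``; counts are
    NB-distributed around the library-size-scaled mean with variance
    ``mu + dispersion * mu**2``.
    """
    config.validate()
    labels = _template_assignments(config)
    rng = _rng(config.seed, "counts")
    states = list(config.states)
    templates = {name: np.asarray(vec, dtype=float) for name, vec in DEFAULT_TEMPLATES.items()}

    n_genes = config.n_genes
    n_samples = len(design)
    state_idx = np.asarray([states.index(s) for s in design["state"]])
    is_male = (design["sex"] == "M").to_numpy()

    lo, hi = config.baseline_logmean_range
    baseline = rng.uniform(lo, hi, size=n_genes)
    sex_off = rng.normal(0.0, config.sex_effect_sd, size=n_genes)
    flo, fhi = config.libsize_factor_range
    lib = np.exp(rng.uniform(np.log(flo), np.log(fhi), size=n_samples))

    profile = np.zeros((n_genes, len(states)))
    for i, lab in enumerate(labels):
        if lab != "null":
            profile[i] = templates[lab]

    log2mu = (
        baseline[:, None]
        + config.amplitude * profile[:, state_idx]
        + sex_off[:, None] * is_male[None, :]
    )
    mu = (2.0 ** log2mu) * lib[None, :]
    r = 1.0 / config.dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)

    gene_ids = [f"gene{i + 1:05d}" for i in range(n_genes)]
    count_df = pd.DataFrame(counts, index=gene_ids, columns=list(design["sample_id"]))
    count_df.index.name = "gene_id"
    truth = pd.DataFrame(
        {
            "unit_id": gene_ids,
            "template": labels,
            "amplitude": [0.0 if lab == "null" else config.amplitude for lab in labels],
            "baseline_log2mean": baseline,
            "sex_offset": sex_off,
        }
    ).set_index("unit_id")
    return count_df, truth


@dataclass
class LsvTemplate:
    """Planted per-state PSI pattern for a group of simulated LSVs.

    ``psi`` has one row per state (in the design's state order) and one
    column per junction; every row must sum to 1.  At most one junction may
    be flagged as a retained intron.
    """

    name: str
    psi: np.ndarray
    retained_intron_index: int | None = None

    def validate(self, n_states: int) -> None:
        psi = np.asarray(self.psi, dtype=float)
        if psi.ndim != 2 or psi.shape[0] != n_states:
            raise ConfigurationError(f"{self.name}: psi must be (n_states, n_junctions)")
        if not 2 <= psi.shape[1] <= 4:
            raise ConfigurationError(f"{self.name}: LSVs carry 2-4 junctions")
        if not np.allclose(psi.sum(axis=1), 1.0, atol=1e-8):
            raise ConfigurationError(f"{self.name}: each state's psi must sum to 1")
        if np.any(psi < 0):
            raise ConfigurationError(f"{self.name}: psi must be non-negative")
        if self.retained_intron_index is not None and not (
            0 <= self.retained_intron_index < psi.shape[1]
        ):
            raise ConfigurationError(f"{self.name}: retained_intron_index out of range")


def gen_lsv_counts(
    design: pd.DataFrame,
    n_lsv: int,
    psi_templates: list[LsvTemplate],
    coverage_mean: float,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample junction counts for simulated LSVs, plus a truth table.

    Each sample's total count is Poisson(coverage_mean) and is split over
    the LSV's junctions with a multinomial at the planted per-state PSI.
    The long-format table carries planted genomic coordinates so that
    control-intron selection can be exercised.
    """
    config.validate()
    if not psi_templates:
        raise ConfigurationError("psi_templates must not be empty")
    n_states = len(config.states)
    for t in psi_templates:
        t.validate(n_states)
    rng = _rng(config.seed, "lsv")
    states = list(config.states)
    state_idx = {s: states.index(s) for s in states}

    rows = []
    truth_rows = []
    pos = 1000
    for i in range(n_lsv):
        tmpl = psi_templates[i % len(psi_templates)]
        psi = np.asarray(tmpl.psi, dtype=float)
        n_j = psi.shape[1]
        lsv_id = f"lsv{i + 1:04d}"
        gene_id = f"lsvgene{i + 1:04d}"
        width = 500
        junction_meta = []
        for j in range(n_j):
            junction_meta.append(
                {
                    "junction_id": f"J{j + 1}",
                    "is_retained_intron": int(j == tmpl.retained_intron_index),
                    "chrom": "chr1",
                    "strand": "+",
                    "start": pos + j * 10,
                    "end": pos + width + j * 10,
                }
            )
        pos += 2 * width + 100

        total_by_sample = {}
        for r in design.itertuples():
            total = int(rng.poisson(coverage_mean))
            total_by_sample[r.sample_id] = total
            draws = (
                rng.multinomial(total, psi[state_idx[r.state]])
                if total > 0
                else np.zeros(n_j, dtype=int)
            )
            for j, meta in enumerate(junction_meta):
                rows.append(
                    {
                        "lsv_id": lsv_id,
                        "gene_id": gene_id,
                        "junction_id": meta["junction_id"],
                        "is_retained_intron": meta["is_retained_intron"],
                        "chrom": meta["chrom"],
                        "strand": meta["strand"],
                        "start": meta["start"],
                        "end": meta["end"],
                        "sample": r.sample_id,
                        "count": int(draws[j]),
                    }
                )
        truth_rows.append(
            {
                "unit_id": lsv_id,
                "template": tmpl.name,
                "n_junctions": n_j,
                "retained_intron_index": (
                    -1 if tmpl.retained_intron_index is None else tmpl.retained_intron_index
                ),
                "psi": ";".join(
                    ",".join(f"{v:.6g}" for v in psi[s]) for s in range(n_states)
                ),
                "uninformative": int(all(v == 0 for v in total_by_sample.values())),
            }
        )
    lsv_df = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows).set_index("unit_id")
    return lsv_df, truth


def gen_annotation_fixture(seed: int = 0):
    """Small three-source annotation trio engineered to exercise every
    merge-rule branch, together with the hand-constructed expected result.

    Returns ``(primary, secondary, novel, evidence, expected)`` where
    ``expected`` is the exact merged transcript list (after secondary
    supplementation, novel integration and splice-evidence reassignment)
    with final gene ids and provenance sources.
    """
    TM = TranscriptModel
    primary = [
        # multi-exon reference gene with two introns
        TM("TP1", "GP1", "chr1", "+", ((1000, 1200), (1500, 1800), (2500, 2800)), "primary"),
        # 800 nt single-exon reference
        TM("TP2", "GP2", "chr1", "+", ((10000, 10800),), "primary"),
        # minus-strand reference
        TM("TP3", "GP3", "chr1", "-", ((20000, 20300), (21000, 21400)), "primary"),
    ]
    secondary = [
        # no overlap with anything -> kept
        TM("TS1", "GS1", "chr1", "+", ((5000, 5400),), "secondary"),
        # 760 nt single exon, reciprocal overlap 0.95 with TP2 -> dropped
        TM("TS2", "GS2", "chr1", "+", ((10040, 10800),), "secondary"),
        # 800 nt single exon, reciprocal overlap 0.50 with TP2 -> kept
        TM("TS3", "GS3", "chr1", "+", ((10400, 11200),), "secondary"),
        # multi-exon overlapping primary exons -> dropped
        TM("TS4", "GS4", "chr1", "+", ((1100, 1250), (1500, 1600)), "secondary"),
        # long (1500 nt) single exon overlapping a primary exon -> dropped
        TM("TS5", "GS5", "chr1", "+", ((2000, 3500),), "secondary"),
        # same coordinates as TP3 exon but opposite strand -> kept (strand rule)
        TM("TS6", "GS6", "chr1", "+", ((20000, 20400),), "secondary"),
    ]
    novel = [
        # intergenic, no evidence -> kept with its own gene id
        TM("TN1", "GN1", "chr1", "+", ((30000, 30200), (30500, 30700)), "novel"),
        # exon inside TP1 intron 2, spliced to TP1 exon 3 -> reassigned to GP1
        TM("TN2", "GN2", "chr1", "+", ((1900, 2100),), "novel"),
        # wholly inside TP1 intron 1, no evidence -> removed
        TM("TN3", "GN3", "chr1", "+", ((1250, 1450),), "novel"),
        # multi-exon, overlaps TP1 exons -> dropped at integration
        TM("TN4", "GN4", "chr1", "+", ((1000, 1150), (1500, 1700)), "novel"),
    ]
    evidence = [
        JunctionEvidence("chr1", "+", donor=2099, acceptor=2500, count=3),
    ]
    from dataclasses import replace

    expected = primary + [secondary[0], secondary[2], secondary[5]] + [
        novel[0],
        replace(novel[1], gene_id="GP1"),
    ]
    return primary, secondary, novel, evidence, expected


@dataclass
class PlantSpec:
    """What to plant into generated sequences."""

    gc: float = 0.5
    n_pentamers: int = 0
    pentamer_spacing: int | None = None  # start-to-start distance when > 1 planted
    motif: str | None = None
    n_motif: int = 0
    utr5_frac: float = 0.2
    cds_frac: float = 0.5


_PENTAMER = "ATTTA"


def _scrub(seq: list[str], pattern: str, rng: np.random.Generator, protected: set[int]) -> None:
    """Destroy accidental occurrences of ``pattern`` outside protected spans."""
    m = len(pattern)
    i = 0
    s = "".join(seq)
    while True:
        idx = s.find(pattern, i)
        if idx == -1:
            break
        span = set(range(idx, idx + m))
        if span & protected:
            i = idx + 1
            continue
        # swap the middle base for one breaking the match
        j = idx + m // 2
        seq[j] = "G" if seq[j] in "AT" else "A"
        s = "".join(seq)
        i = idx
    return


def gen_sequences(
    n: int, length: int, planted: PlantSpec, seed: int = 0
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Sequences with a controlled GC fraction and planted elements.

    Returns ``(sequences, regions, truth)``: sequences keyed by id, a
    region table marking 5'UTR/CDS/3'UTR spans (0-based half-open), and a
    truth table of planted element counts.  Pentamers are planted inside
    the 3'UTR; motifs anywhere in the sequence.
    """
    if length < 1:
        raise ConfigurationError("length must be >= 1")
    for elem in (_PENTAMER, planted.motif or ""):
        if elem and len(elem) > length:
            raise ConfigurationError(f"planted element {elem!r} longer than sequence")
    rng = _rng(seed, "sequences")
    seqs: dict[str, str] = {}
    region_rows = []
    truth_rows = []
    for i in range(n):
        sid = f"seq{i + 1:04d}"
        gc_draw = rng.random(length)
        half = rng.random(length) < 0.5
        seq = [
            ("G" if h else "C") if d < planted.gc else ("A" if h else "T")
            for d, h in zip(gc_draw, half)
        ]
        u5 = int(length * planted.utr5_frac)
        cds_end = u5 + int(length * planted.cds_frac)
        protected: set[int] = set()

        # plant pentamers in the 3' UTR
        if planted.n_pentamers > 0:
            utr3_len = length - cds_end
            spacing = planted.pentamer_spacing or (len(_PENTAMER) + 20)
            need = (planted.n_pentamers - 1) * spacing + len(_PENTAMER)
            if need > utr3_len:
                raise ConfigurationError("planted pentamers do not fit in the 3'UTR")
            start = cds_end + int(rng.integers(0, utr3_len - need + 1))
            for k in range(planted.n_pentamers):
                p = start + k * spacing
                seq[p : p + len(_PENTAMER)] = list(_PENTAMER)
                protected.update(range(p, p + len(_PENTAMER)))
        _scrub(seq, _PENTAMER, rng, protected)

        if planted.motif and planted.n_motif > 0:
            m = len(planted.motif)
            placed = 0
            attempts = 0
            while placed < planted.n_motif and attempts < 1000:
                p = int(rng.integers(0, length - m + 1))
                if set(range(p, p + m)) & protected:
                    attempts += 1
                    continue
                seq[p : p + m] = list(planted.motif)
                protected.update(range(p, p + m))
                placed += 1
            if placed < planted.n_motif:
                raise ConfigurationError("could not place all motifs")
            # motif planting may have re-created pentamers outside the motif
            _scrub(seq, _PENTAMER, rng, protected)

        s = "".join(seq)
        seqs[sid] = s
        region_rows += [
            {"transcript": sid, "region": "5UTR", "start": 0, "end": u5},
            {"transcript": sid, "region": "CDS", "start": u5, "end": cds_end},
            {"transcript": sid, "region": "3UTR", "start": cds_end, "end": length},
        ]
        truth_rows.append(
            {
                "unit_id": sid,
                "gc_target": planted.gc,
                "n_pentamers": planted.n_pentamers,
                "n_motif": planted.n_motif if planted.motif else 0,
                "motif": planted.motif or "",
            }
        )
    return seqs, pd.DataFrame(region_rows), pd.DataFrame(truth_rows).set_index("unit_id")


# ---------------------------------------------------------------------------
# plain-text writers / readers


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t")


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, index=False)


def read_design(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_lsv_table(lsv_df: pd.DataFrame, path) -> None:
    lsv_df.to_csv(path, sep="\t", index=False)


def read_lsv_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
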