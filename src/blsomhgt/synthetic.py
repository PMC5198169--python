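"""Synthetic genomes with planted horizontal transfers.

Host and donor genomes are drawn from low-order Markov chains with controlled
oligonucleotide composition, so every pipeline stage can be exercised — and
scored against a known truth table — without any sequence download.  The
default scenario emulates the structure of a real scan: one insect-like host
genome at GC 0.50, a large compositionally distinct reference collection
organised into pseudo-phyla and pseudo-genera, and donor fragments planted
into host contigs.  One of the pseudo-phyla shares the host's G+C content and
differs only in higher-order structure (a strong AA/TT persistence), probing
the claim that oligonucleotide signatures separate taxa that G+C% cannot.

All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .composition import SequenceRecord, SourceClass

_BASES = "ACGT"


@dataclass(frozen=True)
class GenomeModel:
    """A base-composition model: order-0 frequencies or an order-1 chain.

    ``params`` is a length-4 base-frequency vector for order 0, or a 4x4
    row-stochastic transition matrix (rows/columns in A, C, G, T order) for
    order 1.
    """

    label: str
    order: int
    params: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.params, dtype=np.float64)
        object.__setattr__(self, "params", p)
        if self.order == 0:
            if p.shape != (4,):
                raise ValueError("order-0 model needs 4 base frequencies")
            rows = p[None, :]
        elif self.order == 1:
            if p.shape != (4, 4):
                raise ValueError("order-1 model needs a 4x4 transition matrix")
            rows = p
        else:
            raise ValueError("only Markov orders 0 and 1 are supported")
        if (rows < 0).any() or np.abs(rows.sum(axis=1) - 1.0).max() > 1e-12:
            raise ValueError(f"model {self.label!r}: rows must be stochastic")

    def stationary(self) -> np.ndarray:
        """Stationary base distribution of the chain."""
        if self.order == 0:
            return self.params
        vals, vecs = np.linalg.eig(self.params.T)
        v = np.real(vecs[:, np.argmin(np.abs(vals - 1.0))])
        return v / v.sum()

    @property
    def gc(self) -> float:
        pi = self.stationary()
        return float(pi[1] + pi[2])


def simulate_genome(model: GenomeModel, length: int, seed) -> str:
    """Draw a sequence of ``length`` bases from the model's Markov chain."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if model.order == 0:
        cum = np.cumsum(model.params)
        states = np.searchsorted(cum, rng.random(length), side="right").clip(0, 3)
        return states.astype(np.uint8).tobytes().translate(_STATE_TO_BASE).decode()
    cum = np.cumsum(model.params, axis=1)
    u = rng.random(length)
    # candidate next state for every position under each possible current state;
    # the sequential pass below then just follows the chain through the table
    cand = [np.searchsorted(cum[s], u, side="right").clip(0, 3).tolist() for s in range(4)]
    s = int(np.searchsorted(np.cumsum(model.stationary()), rng.random(), side="right").clip(0, 3))
    out = bytearray(length)
    for t in range(length):
        s = cand[s][t]
        out[t] = s
    return bytes(out).translate(_STATE_TO_BASE).decode()


_STATE_TO_BASE = bytes.maketrans(bytes(range(4)), _BASES.encode())


@dataclass
class PlantedTruth:
    """One planted donor insert: where it sits and where it came from."""

    contig_id: str
    insert_start: int  # 0-based half-open
    insert_end: int
    phylum: str
    genus: Optional[str] = None


class PackingError(RuntimeError):
    pass


def plant_hgt(
    host_records: Sequence[SequenceRecord],
    donors: Sequence[tuple[str, Optional[str], GenomeModel]],
    n_inserts: int,
    insert_len: tuple[int, int],
    seed,
) -> tuple[list[SequenceRecord], list[PlantedTruth]]:
    """Replace random non-overlapping host regions with donor-model sequence.

    ``donors`` rows are (phylum, genus, model); each insert draws a donor
    uniformly, a length uniformly from ``insert_len`` (inclusive), and a
    uniform non-overlapping position.  Replacement (rather than insertion)
    keeps contig coordinates stable, so truth intervals line up with windows
    of the unmodified contigs.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lmin, lmax = insert_len
    if not 0 < lmin <= lmax:
        raise ValueError("invalid insert length range")
    if host_records and lmax > min(len(r) for r in host_records):
        raise ValueError("insert length exceeds the shortest contig")
    seqs = {r.id: bytearray(r.sequence.encode()) for r in host_records}
    occupied: dict[str, list[tuple[int, int]]] = {r.id: [] for r in host_records}
    ids = [r.id for r in host_records]
    truths: list[PlantedTruth] = []
    for _ in range(n_inserts):
        phylum, genus, model = donors[int(rng.integers(len(donors)))]
        L = int(rng.integers(lmin, lmax + 1))
        placed = False
        for _try in range(2000):
            cid = ids[int(rng.integers(len(ids)))]
            clen = len(seqs[cid])
            if clen < L:
                continue
            s = int(rng.integers(0, clen - L + 1))
            if any(s < e and o_s < s + L for o_s, e in occupied[cid]):
                continue
            seqs[cid][s:s + L] = simulate_genome(model, L, rng).encode()
            occupied[cid].append((s, s + L))
            truths.append(PlantedTruth(cid, s, s + L, phylum, genus))
            placed = True
            break
        if not placed:
            raise PackingError(
                "could not place all inserts without overlap; "
                "use fewer or shorter inserts"
            )
    chimeric = [
        SequenceRecord(
            id=r.id, sequence=seqs[r.id].decode(), source_class=SourceClass.HOST
        )
        for r in host_records
    ]
    truths.sort(key=lambda t: (t.contig_id, t.insert_start))
    return chimeric, truths


# ---------------------------------------------------------------------------
# scoring


@dataclass
class EvaluationReport:
    """Segment- and contig-level scores of a scan against the planted truth."""

    tp: int
    fp: int
    fn: int
    segment_recall: float
    segment_precision: Optional[float]  # None when there are zero candidates
    contig_accuracy: Optional[float]    # None when no contig carries an insert
    recall_by_phylum: dict[str, float]
    confusion: pd.DataFrame  # rows: true donor phylum; columns: predicted


def _overlap(a0: int, a1: int, intervals: Sequence[tuple[int, int]]) -> int:
    return sum(max(0, min(a1, e) - max(a0, s)) for s, e in intervals)


def evaluate(
    assignments,
    contig_calls,
    truth: Sequence[PlantedTruth],
    overlap_rule: float = 0.5,
) -> EvaluationReport:
    """Score candidate calls against the planted truth.

    A mapped segment is truth-covered when at least ``overlap_rule`` of its
    length overlaps planted intervals; a candidate segment is a true positive
    iff it is truth-covered.  Recall is TP over truth-covered segments,
    precision TP over candidates (None when there are no candidates).  Contig
    accuracy is the fraction of insert-bearing contigs whose assigned phylum
    equals the majority (base-weighted) donor phylum.
    """
    by_contig: dict[str, list[PlantedTruth]] = {}
    for t in truth:
        by_contig.setdefault(t.contig_id, []).append(t)
    known = {a.segment.contig_id for a in assignments}
    missing = set(by_contig) - known
    if missing and known:
        raise ValueError(f"truth refers to unknown contigs: {sorted(missing)[:5]}")

    tp = fp = fn = 0
    cov_by_phylum: dict[str, int] = {}
    tp_by_phylum: dict[str, int] = {}
    conf: dict[tuple[str, str], int] = {}
    for a in assignments:
        seg = a.segment
        ivals = [(t.insert_start, t.insert_end) for t in by_contig.get(seg.contig_id, [])]
        ov = _overlap(seg.start, seg.end, ivals)
        covered = ov >= overlap_rule * (seg.end - seg.start)
        if covered:
            # dominant donor at this segment, by overlapped bases
            per = {
                t.phylum: _overlap(seg.start, seg.end, [(t.insert_start, t.insert_end)])
                for t in by_contig[seg.contig_id]
            }
            donor = max(sorted(per), key=lambda p: per[p])
            cov_by_phylum[donor] = cov_by_phylum.get(donor, 0) + 1
            if not a.is_hgt_candidate:
                pred = "(not called)"
            elif a.phylum is None:
                pred = "(no phylum)"
            else:
                pred = a.phylum
            conf[(donor, pred)] = conf.get((donor, pred), 0) + 1
            if a.is_hgt_candidate:
                tp += 1
                tp_by_phylum[donor] = tp_by_phylum.get(donor, 0) + 1
            else:
                fn += 1
        elif a.is_hgt_candidate:
            fp += 1

    n_cov = tp + fn
    recall = tp / n_cov if n_cov else 0.0
    n_cand = tp + fp
    precision = tp / n_cand if n_cand else None
    recall_by_phylum = {
        p: tp_by_phylum.get(p, 0) / n for p, n in sorted(cov_by_phylum.items())
    }

    calls_by_contig = {c.contig_id: c for c in contig_calls}
    n_truth_contigs = 0
    n_correct = 0
    for cid, ts in by_contig.items():
        bases: dict[str, int] = {}
        for t in ts:
            bases[t.phylum] = bases.get(t.phylum, 0) + (t.insert_end - t.insert_start)
        major = max(sorted(bases), key=lambda p: bases[p])
        n_truth_contigs += 1
        call = calls_by_contig.get(cid)
        if call is not None and call.assigned_phylum == major:
            n_correct += 1
    accuracy = n_correct / n_truth_contigs if n_truth_contigs else None

    donors = sorted({d for d, _ in conf})
    preds = sorted({p for _, p in conf})
    confusion = pd.DataFrame(
        [[conf.get((d, p), 0) for p in preds] for d in donors],
        index=donors,
        columns=preds,
        dtype=int,
    )
    return EvaluationReport(
        tp=tp,
        fp=fp,
        fn=fn,
        segment_recall=recall,
        segment_precision=precision,
        contig_accuracy=accuracy,
        recall_by_phylum=recall_by_phylum,
        confusion=confusion,
    )


# ---------------------------------------------------------------------------
# the default study scenario


#: symmetric (hence doubly stochastic: GC exactly 0.50) order-1 host chain
#: with mild CpG-like depletion, standing in for an insect genome
HOST_TRANSITIONS = np.array(
    [
        [0.28, 0.24, 0.22, 0.26],
        [0.24, 0.28, 0.18, 0.30],
        [0.22, 0.18, 0.32, 0.28],
        [0.26, 0.30, 0.28, 0.16],
    ]
)

PHYLUM_AT = "Pseudophylum_lowGC"
PHYLUM_GC = "Pseudophylum_highGC"
PHYLUM_ISO = "Pseudophylum_isoGC"

#: per-genus shifts around each pseudo-phylum's central composition
_GENUS_GC_OFFSETS = (-0.06, -0.02, 0.02, 0.06)
_GENUS_AA_PERSISTENCE = (0.39, 0.43, 0.47, 0.51)


def _order0_model(label: str, gc: float) -> GenomeModel:
    at = (1.0 - gc) / 2.0
    return GenomeModel(label, 0, np.array([at, gc / 2, gc / 2, at]))


def _iso_gc_model(label: str, aa: float) -> GenomeModel:
    """Order-1 chain at GC 0.50 with AA/TT persistence ``aa``.

    The matrix is symmetric (doubly stochastic), so G+C content matches the
    host exactly; only higher-order word statistics differ.
    """
    at = 0.75 - aa
    m = np.array(
        [
            [aa, 0.125, 0.125, at],
            [0.125, 0.375, 0.375, 0.125],
            [0.125, 0.375, 0.375, 0.125],
            [at, 0.125, 0.125, aa],
        ]
    )
    return GenomeModel(label, 1, m)


def reference_models() -> dict[str, dict[str, GenomeModel]]:
    """phylum -> genus -> model for the default pseudo-reference collection."""
    out: dict[str, dict[str, GenomeModel]] = {PHYLUM_AT: {}, PHYLUM_GC: {}, PHYLUM_ISO: {}}
    for g, off in enumerate(_GENUS_GC_OFFSETS, start=1):
        name = f"{PHYLUM_AT}_genus{g}"
        out[PHYLUM_AT][name] = _order0_model(name, 0.35 + off)
        name = f"{PHYLUM_GC}_genus{g}"
        out[PHYLUM_GC][name] = _order0_model(name, 0.65 + off)
    for g, aa in enumerate(_GENUS_AA_PERSISTENCE, start=1):
        name = f"{PHYLUM_ISO}_genus{g}"
        out[PHYLUM_ISO][name] = _iso_gc_model(name, aa)
    return out


@dataclass
class Scenario:
    """A complete synthetic study: inputs, truth, and the generating models."""

    host_records: list[SequenceRecord]       # chimeric contigs (inserts planted)
    ref_records: list[SequenceRecord]
    truth: list[PlantedTruth]
    host_model: GenomeModel
    models: dict[str, dict[str, GenomeModel]]
    seed: int


def scenario(
    seed: int,
    n_contigs: int = 30,
    contig_len: int = 50_000,
    reference_len: int = 1_960_000,
    n_inserts: int = 40,
    insert_len: tuple[int, int] = (5_000, 10_000),
) -> Scenario:
    """Generate a synthetic study with planted transfers.

    Defaults give 30 host contigs of 50 kb and 12 reference pseudo-genomes of
    1.96 Mb (3 pseudo-phyla x 4 pseudo-genera), i.e. about 5,000 training
    fragments at a 5 kb fragment size — a reference collection that outweighs
    the host, as in a real scan against a large genome database.
    """
    root = np.random.default_rng(seed)
    host_model = GenomeModel("host", 1, HOST_TRANSITIONS)
    models = reference_models()

    host = [
        SequenceRecord(
            id=f"contig{n:03d}",
            sequence=simulate_genome(host_model, contig_len, root),
            source_class=SourceClass.HOST,
        )
        for n in range(1, n_contigs + 1)
    ]
    refs = [
        SequenceRecord(
            id=f"ref_{genus}",
            sequence=simulate_genome(model, reference_len, root),
            source_class=SourceClass.REFERENCE,
            phylum=phylum,
            genus=genus,
        )
        for phylum, genera in models.items()
        for genus, model in genera.items()
    ]
    donors = [
        (phylum, genus, model)
        for phylum, genera in models.items()
        for genus, model in genera.items()
    ]
    chimeric, truth = plant_hgt(host, donors, n_inserts, insert_len, root)
    return Scenario(
        host_records=chimeric,
        ref_records=refs,
        truth=truth,
        host_model=host_model,
        models=models,
        seed=seed,
    )


def default_scenario(seed: int) -> Scenario:
    """The default study conditions (see ``scenario`` for the sizes)."""
    return scenario(seed)


def truth_table(truth: Sequence[PlantedTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig_id": t.contig_id,
                "insert_start": t.insert_start,
                "insert_end": t.insert_end,
                "phylum": t.phylum,
                "genus": t.genus if t.genus is not None else "",
            }
            for t in truth
        ],
        columns=["contig_id", "insert_start", "insert_end", "phylum", "genus"],
    )
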