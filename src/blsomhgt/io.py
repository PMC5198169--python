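"""Readers, writers, and run configuration.

File conventions: FASTA input (gzip transparent) parsed with Biopython; a
tab-separated taxonomy table with columns ``seq_id  phylum  genus`` (genus
may be empty); tab-separated per-segment and per-contig reports with 1-based
inclusive coordinates (internally everything is 0-based half-open); lattices
as self-describing structured text; a plain-text manifest echoing the full
configuration and input checksums so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import gzip
import hashlib
import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .blsom import TrainingConfig
from .composition import Segment, SequenceRecord, SourceClass, sanitize_sequence
from .pipeline import PipelineResult, SegmentAssignment, Territory, TerritoryMap
from .synthetic import PlantedTruth

logger = logging.getLogger("blsomhgt")


@dataclass
class RunConfig:
    """All pipeline parameters, echoed verbatim into every output header.

    Defaults follow the standard scan settings: degenerate tetranucleotides
    (k=4), 5 kb windows with a 1 kb step, windows with more than 10% N
    omitted, contigs strictly longer than 5 kb analysed, references with at
    least 10 kb of sequence used, and contigs assigned to a taxon when it
    holds strictly more than 40% of their candidate segments.
    """

    k: int = 4
    window: int = 5000
    step: int = 1000
    n_fraction_max: float = 0.10
    min_contig: int = 5001
    min_reference_total: int = 10_000
    contig_threshold: float = 0.40
    min_candidates: int = 1
    contig_denominator: str = "candidates"
    lattice_width: Optional[int] = None  # None = size from nodes_per_vector
    epochs: int = 100
    alpha0: float = 0.6
    alpha_min: float = 0.01
    beta0: Optional[float] = None
    init_span: float = 2.5
    nodes_per_vector: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1 or self.window <= 0 or self.step <= 0:
            raise ValueError("k, window and step must be positive")
        if not 0 <= self.n_fraction_max < 1:
            raise ValueError("n_fraction_max must be in [0, 1)")
        if not 0 < self.contig_threshold < 1:
            raise ValueError("contig_threshold must be in (0, 1)")
        self.training_config()  # validates the training fields

    def training_config(self) -> TrainingConfig:
        return TrainingConfig(
            epochs=self.epochs,
            alpha0=self.alpha0,
            alpha_min=self.alpha_min,
            beta0=self.beta0,
            init_span=self.init_span,
            nodes_per_vector=self.nodes_per_vector,
        )

    def to_text(self) -> str:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in dataclasses.fields(self)]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse a ``key = value`` config file; unknown keys are rejected."""
        known = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            kwargs[key] = _parse_value(value)
        return cls(**kwargs)


def _parse_value(s: str):
    if s in ("None", ""):
        return None
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            pass
    return s


# ---------------------------------------------------------------------------
# sequence + taxonomy input


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path, source_class: SourceClass = SourceClass.HOST) -> list[SequenceRecord]:
    """Read a (possibly gzipped) multi-FASTA into sanitized records.

    Record ids are the first whitespace-delimited token of the header.
    Lower-case (soft-masked) bases are upper-cased and IUPAC ambiguity codes
    other than N are converted to N with a warning.
    """
    records = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            try:
                seq = sanitize_sequence(str(rec.seq), rec.id)
            except ValueError as exc:
                raise ValueError(f"{path}: {exc}") from exc
            records.append(SequenceRecord(id=rec.id, sequence=seq, source_class=source_class))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[SequenceRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.sequence), width):
                fh.write(r.sequence[i:i + width] + "\n")


def read_taxonomy(path) -> dict[str, tuple[str, Optional[str]]]:
    """seq_id -> (phylum, genus-or-None) from a headered TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["seq_id", "phylum", "genus"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"{path}: expected columns {required}, got {list(df.columns)}")
    if df["seq_id"].duplicated().any():
        dups = df.loc[df["seq_id"].duplicated(), "seq_id"].tolist()
        raise ValueError(f"{path}: duplicate seq_id entries: {dups[:5]}")
    out = {}
    for _, row in df.iterrows():
        if not row["phylum"]:
            raise ValueError(f"{path}: record {row['seq_id']!r} lacks a phylum")
        out[row["seq_id"]] = (row["phylum"], row["genus"] or None)
    return out


def attach_taxonomy(
    records: Sequence[SequenceRecord], taxonomy: dict[str, tuple[str, Optional[str]]]
) -> list[SequenceRecord]:
    """Return reference records with phylum/genus filled from the taxonomy table.

    Every FASTA id must have a taxonomy row; taxonomy rows without a FASTA
    record are ignored with a warning.
    """
    missing = [r.id for r in records if r.id not in taxonomy]
    if missing:
        raise ValueError(f"reference records lacking a taxonomy row: {missing[:5]}")
    unused = set(taxonomy) - {r.id for r in records}
    if unused:
        logger.warning("%d taxonomy rows have no FASTA record; ignored", len(unused))
    return [
        SequenceRecord(
            id=r.id,
            sequence=r.sequence,
            source_class=SourceClass.REFERENCE,
            phylum=taxonomy[r.id][0],
            genus=taxonomy[r.id][1],
        )
        for r in records
    ]


def write_taxonomy(records: Sequence[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tphylum\tgenus\n")
        for r in records:
            fh.write(f"{r.id}\t{r.phylum or ''}\t{r.genus or ''}\n")


def write_truth(truth: Sequence[PlantedTruth], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tinsert_start\tinsert_end\tphylum\tgenus\n")
        for t in truth:
            fh.write(
                f"{t.contig_id}\t{t.insert_start}\t{t.insert_end}\t{t.phylum}\t{t.genus or ''}\n"
            )


def read_truth(path) -> list[PlantedTruth]:
    df = pd.read_csv(path, sep="\t", dtype={"contig_id": str}, keep_default_na=False)
    return [
        PlantedTruth(
            contig_id=row.contig_id,
            insert_start=int(row.insert_start),
            insert_end=int(row.insert_end),
            phylum=row.phylum,
            genus=row.genus or None,
        )
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# report output (1-based inclusive coordinates in user-facing tables)


def segment_table(result: PipelineResult) -> pd.DataFrame:
    rows = []
    for a in result.assignments:
        s = a.segment
        rows.append(
            {
                "contig": s.contig_id,
                "start": s.start + 1,
                "end": s.end,
                "node_i": a.node[0],
                "node_j": a.node[1],
                "territory": a.territory.name.lower(),
                "phylum": a.phylum or "",
                "genus": a.genus or "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["contig", "start", "end", "node_i", "node_j", "territory", "phylum", "genus"],
    )


def contig_table(result: PipelineResult) -> pd.DataFrame:
    rows = []
    for c in result.contig_calls:
        rows.append(
            {
                "contig": c.contig_id,
                "n_segments": c.n_segments_total,
                "n_candidate_segments": c.n_candidate_segments,
                "top_fraction": round(c.top_fraction, 6),
                "assigned_phylum": c.assigned_phylum or "Unassigned",
                "assigned_genus": c.assigned_genus or "Unassigned",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "contig",
            "n_segments",
            "n_candidate_segments",
            "top_fraction",
            "assigned_phylum",
            "assigned_genus",
        ],
    )


def assignments_from_segment_table(df: pd.DataFrame) -> list[SegmentAssignment]:
    """Rebuild lightweight segment assignments from a per-segment report.

    Composition vectors are not stored in reports, so the returned
    assignments support contig calling and summarising but not re-mapping.
    """
    out = []
    for row in df.itertuples():
        seg = Segment(
            contig_id=str(row.contig),
            start=int(row.start) - 1,
            end=int(row.end),
            n_count=0,
            composition=None,
            omitted=False,
        )
        terr = Territory[str(row.territory).upper()]
        phylum = str(row.phylum) if isinstance(row.phylum, str) and row.phylum else None
        genus = str(row.genus) if isinstance(row.genus, str) and row.genus else None
        out.append(
            SegmentAssignment(
                segment=seg,
                node=(int(row.node_i), int(row.node_j)),
                territory=terr,
                is_hgt_candidate=terr == Territory.PROKARYOTE,
                phylum=phylum,
                genus=genus,
            )
        )
    return out


def write_territories(tmap: TerritoryMap, path) -> None:
    """Territory map as TSV: per-node class, majority phylum, and tallies."""
    with open(path, "w") as fh:
        fh.write("# blsomhgt-territories v1\n")
        fh.write("# phyla=" + ",".join(tmap.phyla) + "\n")
        cols = ["i", "j", "territory", "node_phylum", "host_count"] + [
            f"n_{p}" for p in tmap.phyla
        ]
        fh.write("\t".join(cols) + "\n")
        I, J = tmap.host_count.shape
        for i in range(I):
            for j in range(J):
                row = [
                    str(i),
                    str(j),
                    Territory(int(tmap.territory[i, j])).name.lower(),
                    tmap.node_phylum[i, j] or "",
                    str(int(tmap.host_count[i, j])),
                ] + [str(int(tmap.ref_counts[n, i, j])) for n in range(len(tmap.phyla))]
                fh.write("\t".join(row) + "\n")


def read_territories(path) -> TerritoryMap:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != "# blsomhgt-territories v1":
        raise ValueError(f"{path}: not a territory file")
    phyla = tuple(p for p in lines[1].split("=", 1)[1].split(",") if p)
    body = [ln.split("\t") for ln in lines[3:]]
    I = max(int(r[0]) for r in body) + 1
    J = max(int(r[1]) for r in body) + 1
    host = np.zeros((I, J), dtype=np.int64)
    refs = np.zeros((len(phyla), I, J), dtype=np.int64)
    terr = np.zeros((I, J), dtype=np.int8)
    node_phylum = np.full((I, J), None, dtype=object)
    for r in body:
        i, j = int(r[0]), int(r[1])
        terr[i, j] = Territory[r[2].upper()]
        node_phylum[i, j] = r[3] or None
        host[i, j] = int(r[4])
        for n in range(len(phyla)):
            refs[n, i, j] = int(r[5 + n])
    return TerritoryMap(phyla, host, refs, terr, node_phylum)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, cfg: RunConfig, inputs: dict[str, str], extra: Optional[dict] = None):
    """Plain-text manifest: versions, config echo, input checksums."""
    from . import __version__

    doc = {
        "blsomhgt": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "config": {f.name: getattr(cfg, f.name) for f in dataclasses.fields(cfg)},
        "inputs": {name: sha256_file(p) for name, p in inputs.items()},
    }
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2, default=str) + "\n")


TERRITORY_COLORS = {
    Territory.HOST: (0.0, 0.65, 0.0),       # green
    Territory.PROKARYOTE: (0.1, 0.3, 0.9),  # blue
    Territory.MIXED: (0.0, 0.0, 0.0),       # black
    Territory.EMPTY: (1.0, 1.0, 1.0),       # white
}


def render_map(territories, path) -> None:
    """Territory map as an image: host green, prokaryote blue, mixed black,
    empty white."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    terr = territories.territory
    img = np.ones(terr.shape + (3,))
    for t, color in TERRITORY_COLORS.items():
        img[terr == int(t)] = color
    fig, ax = plt.subplots(figsize=(max(3, terr.shape[1] / 10), max(3, terr.shape[0] / 10)))
    ax.imshow(img, interpolation="nearest")
    ax.set_xlabel("j")
    ax.set_ylabel("i")
    ax.set_title("BLSOM territories")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
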