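"""End-to-end comparison pipeline and artifact writing.

``run_compare`` takes >= 1 annotated genomes and emits the study-style
artifact bundle: a genome summary (sizes, region lengths, GC%, gene counts),
the dispersed-repeat and SSR censuses, the junction comparison, the per-locus
variability table with class summaries, the ranked marker table, a
sliding-window identity profile against a reference genome, and a JSON
manifest with checksums.  Reruns with the same config and inputs are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import subprocess
import tempfile
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .hotspot_stats import (LocusAlignment, align_locus, prealigned,
                            select_markers, sliding_identity,
                            variability_table)
from .locus_extract import (ExtractedLocus, LocusDef, LocusSet,
                            collect_homologs, extract_loci)
from .plastome_io import (CircularGenome, GeneFeature, read_annotations,
                          read_fasta, write_fasta)
from .quadripartite import canonicalize, compare_junctions, detect_ir
from .repeat_scan import find_repeats, find_ssrs

logger = logging.getLogger(__name__)

ARTIFACTS = ("genome_summary.tsv", "repeats.tsv", "ssrs.tsv", "junctions.tsv",
             "variability.tsv", "markers.tsv", "identity_profile.tsv")


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {err}")


@dataclass
class RunConfig:
    """Run configuration; all thresholds default to the study's settings."""

    genomes: list[dict]  # {"fasta": ..., "annotations": ..., "format": ...}
    out_dir: str
    min_ir_len: int = 1000
    min_repeat_len: int = 8
    locus_min_len: int = 100
    min_taxa: int | None = None
    top_n_markers: int = 20
    identity_window: int = 100
    identity_step: int = 25
    ir_copies: str = "one"
    reference: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_ir_len", "min_repeat_len", "locus_min_len",
                     "top_n_markers", "identity_window", "identity_step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _coding_pct(genome: CircularGenome, features: Sequence[GeneFeature],
                kinds: tuple[str, ...]) -> float:
    import numpy as np
    mask = np.zeros(genome.length, dtype=bool)
    for f in features:
        if f.kind not in kinds:
            continue
        for p in f.parts:
            if p.wraps:
                mask[p.start :] = True
                mask[: p.end] = True
            else:
                mask[p.start : p.end] = True
    return round(100 * mask.sum() / genome.length, 2)


def _align_whole_genomes(genomes: Sequence[CircularGenome]) -> dict[str, str]:
    """Positional rows when lengths agree, otherwise MAFFT."""
    lengths = {g.length for g in genomes}
    if len(lengths) == 1:
        return {g.id: g.seq for g in genomes}
    if shutil.which("mafft") is None:
        raise RuntimeError("genomes differ in length and mafft is unavailable")
    with tempfile.TemporaryDirectory() as td:
        fin = Path(td) / "in.fasta"
        write_fasta(genomes, fin)
        res = subprocess.run(["mafft", "--retree", "2", "--quiet", str(fin)],
                             capture_output=True, text=True, check=True)
        rows: dict[str, str] = {}
        current = None
        for line in res.stdout.splitlines():
            if line.startswith(">"):
                current = line[1:].split()[0]
                rows[current] = []
            elif current is not None:
                rows[current].append(line.strip().upper())
        return {k: "".join(v) for k, v in rows.items()}


def run_compare(config: RunConfig,
                loaded: Sequence[tuple[CircularGenome,
                                       list[GeneFeature]]] | None = None,
                ) -> Path:
    """Run the full comparison and write the artifact bundle.

    ``loaded`` bypasses file input (used by the synthetic pipeline); otherwise
    genomes and annotations are read from the paths in ``config.genomes``.
    Any stage failure removes partial outputs and raises :class:`StageError`.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out_dir / name
        df.to_csv(path, sep="\t", index=False, float_format="%.2f")
        written.append(path)

    stage = "load"
    try:
        if loaded is None:
            loaded = []
            for entry in config.genomes:
                gs = read_fasta(entry["fasta"])
                for g in gs:
                    feats = []
                    if entry.get("annotations"):
                        feats = read_annotations(
                            entry["annotations"],
                            entry.get("format", "gff3"),
                            genome_length=g.length)
                    loaded.append((g, feats))
        if not loaded:
            raise ValueError("no genomes to compare")

        stage = "quadripartite"
        canon: list[tuple[CircularGenome, list[GeneFeature], object]] = []
        for g, feats in loaded:
            st = detect_ir(g, min_ir_len=config.min_ir_len)
            canon.append(canonicalize(g, feats, st))

        stage = "genome_summary"
        rows = []
        for g, feats, st in canon:
            names = [f.name for f in feats]
            rows.append({
                "genome": g.id, "length": g.length,
                "gc_pct": round(100 * g.gc_fraction(), 2),
                "lsc_length": st.lsc_length, "ssc_length": st.ssc_length,
                "ir_length": st.ir_length,
                "n_genes_total": len(names),
                "n_genes_unique": len(set(names)),
                "coding_pct_cds": _coding_pct(g, feats, ("CDS",)),
                "coding_pct_all": _coding_pct(g, feats, ("CDS", "tRNA", "rRNA")),
            })
        emit("genome_summary.tsv", pd.DataFrame(rows))

        stage = "repeats"
        rrows = []
        for g, feats, st in canon:
            for h in find_repeats(g, min_repeat_len=config.min_repeat_len,
                                  structure=st):
                rrows.append({"genome": g.id, "type": h.rtype,
                              "start1": h.pos1.start + 1, "end1": h.pos1.end,
                              "start2": h.pos2.start + 1, "end2": h.pos2.end,
                              "length": h.length,
                              "is_ir_pair": int(h.is_ir_pair)})
        emit("repeats.tsv", pd.DataFrame(
            rrows, columns=["genome", "type", "start1", "end1", "start2",
                            "end2", "length", "is_ir_pair"]))

        stage = "ssrs"
        srows = []
        for g, feats, st in canon:
            for s in find_ssrs(g):
                srows.append({"genome": g.id, "motif": s.motif, "unit": s.unit,
                              "copies": s.copies, "start": s.locus.start + 1,
                              "end": s.locus.end})
        emit("ssrs.tsv", pd.DataFrame(
            srows, columns=["genome", "motif", "unit", "copies", "start",
                            "end"]))

        stage = "junctions"
        if len(canon) >= 2:
            table, summary = compare_junctions(
                [(g.id, st, feats) for g, feats, st in canon])
            merged = table.merge(summary[["genome", "ir_type"]], on="genome")
            emit("junctions.tsv", merged)
        else:
            emit("junctions.tsv", pd.DataFrame(
                columns=["genome", "junction", "gene", "relation", "distance",
                         "ir_type"]))

        stage = "loci"
        per_taxon: dict[str, list[ExtractedLocus]] = {}
        for g, feats, st in canon:
            loci, report = extract_loci(g, feats, st,
                                        min_len=config.locus_min_len,
                                        ir_copies=config.ir_copies)
            logger.info("%s: %d loci, %d residual bases", g.id, len(loci),
                        report.residual_bases)
            per_taxon[g.id] = loci
        locus_sets = collect_homologs(per_taxon, min_taxa=config.min_taxa)

        stage = "variability"
        alignments = [align_locus(ls) for ls in locus_sets
                      if len(ls.seqs) >= 2]
        if alignments:
            result = variability_table(alignments)
            emit("variability.tsv", result.records)
            markers = select_markers(result.records,
                                     top_n=config.top_n_markers)
            emit("markers.tsv", markers)
        else:
            cols = ["locus", "class", "region", "length_min", "length_max",
                    "aligned_length", "n_vc", "pct_vc", "n_pic", "pct_pic"]
            emit("variability.tsv", pd.DataFrame(columns=cols))
            emit("markers.tsv", pd.DataFrame(columns=cols))

        stage = "identity_profile"
        genomes_only = [g for g, _, _ in canon]
        if len(genomes_only) >= 2:
            rows_wg = _align_whole_genomes(genomes_only)
            ref = config.reference or genomes_only[0].id
            profile = sliding_identity(rows_wg, ref,
                                       window=config.identity_window,
                                       step=config.identity_step)
            emit("identity_profile.tsv", profile)
        else:
            emit("identity_profile.tsv",
                 pd.DataFrame(columns=["taxon", "start", "end", "identity"]))

        stage = "marker_matrix"
        if alignments:
            by_name = {a.locus.name: a for a in alignments}
            chosen = [by_name[nm] for nm in markers["locus"] if nm in by_name]
            if chosen:
                taxa = sorted(chosen[0].rows)
                path = out_dir / "markers_concat.fasta"
                with open(path, "w") as fh:
                    for t in taxa:
                        fh.write(f">{t}\n")
                        fh.write("".join(a.rows[t] for a in chosen) + "\n")
                written.append(path)

        stage = "manifest"
        manifest = {
            "package": "plastocompare",
            "version": __version__,
            "config": asdict(config),
            "files": {p.name: _sha256(p) for p in sorted(written)},
        }
        mpath = out_dir / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return mpath
    except Exception as err:
        for p in written:
            p.unlink(missing_ok=True)
        raise StageError(stage, err) from err


# ---------------------------------------------------------------------------
# per-locus FASTA directory helpers (hotspots CLI input/output)
# ---------------------------------------------------------------------------

def write_locus_dir(locus_sets: Sequence[LocusSet], out_dir: str | Path) -> Path:
    """One unaligned FASTA per locus plus a manifest TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, ls in enumerate(locus_sets):
        fname = f"locus_{i + 1:04d}.fasta"
        with open(out / fname, "w") as fh:
            for taxon, seq in sorted(ls.seqs.items()):
                fh.write(f">{taxon}\n{seq}\n")
        rows.append({"file": fname, "locus": ls.locus.name,
                     "class": ls.locus.lclass, "region": ls.locus.region})
    pd.DataFrame(rows).to_csv(out / "loci.tsv", sep="\t", index=False)
    return out


def read_locus_dir(path: str | Path, prealigned_rows: bool = False,
                   ) -> list[LocusAlignment] | list[LocusSet]:
    """Load a locus directory written by :func:`write_locus_dir` (or any
    directory of per-locus FASTAs; class is then inferred from the name)."""
    path = Path(path)
    manifest = path / "loci.tsv"
    entries: list[tuple[Path, str, str, str]] = []
    if manifest.exists():
        df = pd.read_csv(manifest, sep="\t")
        for _, row in df.iterrows():
            entries.append((path / row["file"], row["locus"], row["class"],
                            row["region"]))
    else:
        for f in sorted(path.glob("*.fasta")):
            name = f.stem
            lclass = ("noncoding" if ("-" in name or "intron" in name)
                      else "coding")
            entries.append((f, name, lclass, "LSC"))
    out = []
    for f, name, lclass, region in entries:
        seqs: dict[str, str] = {}
        current = None
        for line in f.read_text().splitlines():
            if line.startswith(">"):
                current = line[1:].split()[0]
                seqs[current] = ""
            elif current:
                seqs[current] += line.strip().upper()
        locus = LocusDef(name, lclass, region)
        if prealigned_rows:
            out.append(prealigned(locus, seqs))
        else:
            lengths = [len(s.replace("-", "")) for s in seqs.values()]
            out.append(LocusSet(locus, {t: s.replace("-", "")
                                        for t, s in seqs.items()},
                                (min(lengths), max(lengths))))
    return out
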