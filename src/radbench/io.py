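"""Strict readers and writers for the pipeline's plain-text formats.

Expression: TSV, first column gene ID, remaining columns sample IDs.
Dose-response: CSV with columns sample_id,dose_gy,surviving_fraction.
Gene sets: GMT (name, description, tab-separated members).
Profiles/benchmarks: CSV.  Models, reports, ground truth, manifest: JSON.

Parsers reject ragged rows and duplicate identifiers, naming the
offenders, so that write-then-read is the identity on valid files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .dose_response import DoseResponseCurve, curves_from_frame, curves_to_frame
from .enrichment import GeneSet, GeneSetCollection

__all__ = [
    "load_expression",
    "write_expression",
    "load_curves",
    "write_curves",
    "load_gmt",
    "write_gmt",
    "file_sha256",
]


def load_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV, validating identifiers."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ValueError(f"{path}: expected gene column plus >=1 sample column")
        n_cols = len(header)
        sample_ids = header[1:]
        dup_samples = _duplicates(sample_ids)
        if dup_samples:
            raise ValueError(f"{path}: duplicate sample IDs: {dup_samples}")
        genes: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != n_cols:
                raise ValueError(
                    f"{path}:{lineno}: expected {n_cols} fields, got {len(fields)}"
                )
            genes.append(fields[0])
            try:
                rows.append([float(v) for v in fields[1:]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value ({exc})") from None
    dup_genes = _duplicates(genes)
    if dup_genes:
        raise ValueError(f"{path}: duplicate gene IDs: {dup_genes}")
    return pd.DataFrame(rows, index=genes, columns=sample_ids)


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def load_curves(path: str | Path) -> list[DoseResponseCurve]:
    frame = pd.read_csv(path)
    return curves_from_frame(frame)


def write_curves(curves: list[DoseResponseCurve], path: str | Path) -> None:
    curves_to_frame(curves).to_csv(path, index=False, float_format="%.10g")


def load_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file; every line needs a name, description and members."""
    path = Path(path)
    sets: list[GeneSet] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, "
                    "need name, description and >=1 member"
                )
            sets.append(
                GeneSet(name=fields[0], description=fields[1], genes=tuple(fields[2:]))
            )
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(entries: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(entries, indent=1, sort_keys=True))


def _duplicates(items: list[str]) -> list[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for x in items:
        if x in seen:
            dupes.add(x)
        seen.add(x)
    return sorted(dupes)
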