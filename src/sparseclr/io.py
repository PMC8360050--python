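"""Readers and writers for count tables, metadata and results.

Count tables are stored samples-as-rows (first column = sample id, header =
taxon ids); inputs that follow the taxa-as-rows convention (e.g. BIOM) are
transposed on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import CountMatrix, SimDraw

__all__ = [
    "Dataset",
    "read_counts",
    "write_counts",
    "read_metadata",
    "write_truth",
    "read_truth",
]

_SEPS = {".tsv": "\t", ".csv": ",", ".txt": "\t"}


class FormatError(ValueError):
    """Raised for malformed or unsupported on-disk tables."""


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".biom":
        return "biom"
    if suffix in _SEPS:
        return {"\t": "tsv", ",": "csv"}[_SEPS[suffix]]
    raise FormatError(f"cannot infer format from {path.name}; pass format=")


def read_counts(
    path,
    format: str | None = None,
    orientation: str = "samples",
) -> CountMatrix:
    """Read a count table from TSV/CSV/BIOM.

    ``orientation`` is the row convention of the file: ``"samples"`` (rows
    are samples) or ``"taxa"`` (rows are taxa; transposed on read).  Negative
    or non-integer cells and duplicate identifiers are rejected.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if orientation not in ("samples", "taxa"):
        raise ValueError("orientation must be 'samples' or 'taxa'")
    if fmt == "biom":
        try:
            import biom
        except ImportError as exc:  # pragma: no cover
            raise FormatError(
                "reading BIOM requires the 'biom-format' package"
            ) from exc
        table = biom.load_table(str(path))
        # BIOM stores observations (taxa) as rows
        df = table.to_dataframe(dense=True).T
    else:
        sep = "\t" if fmt == "tsv" else ","
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        if len(set(header)) != len(header):   # pandas silently mangles these
            raise FormatError(f"duplicate identifiers in {path}")
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:
            raise FormatError(f"could not parse {path}: {exc}") from exc
        if orientation == "taxa":
            df = df.T
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise FormatError(f"duplicate identifiers in {path}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError(f"non-numeric cells in {path}")
    if (values < 0).any():
        raise FormatError(f"negative counts in {path}")
    if not np.array_equal(values, np.floor(values)):
        raise FormatError(f"non-integer counts in {path}")
    return CountMatrix(values.astype(np.int64),
                       df.index.astype(str).to_numpy(),
                       df.columns.astype(str).to_numpy())


def write_counts(Y: CountMatrix, path, format: str | None = None) -> None:
    """Write a count table as TSV/CSV, samples as rows."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt not in ("tsv", "csv"):
        raise FormatError(f"unsupported output format {fmt!r}")
    Y.to_frame().to_csv(path, sep="\t" if fmt == "tsv" else ",")


def read_metadata(path, format: str | None = None) -> pd.DataFrame:
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt not in ("tsv", "csv"):
        raise FormatError(f"unsupported metadata format {fmt!r}")
    return pd.read_csv(path, sep="\t" if fmt == "tsv" else ",", index_col=0)


def write_truth(draw: SimDraw, Y: CountMatrix, path) -> None:
    """Write the latent truth of a simulated draw as two TSV blocks.

    ``<path>`` gets the per-sample truth (x, a); ``<stem>.taxa.tsv`` the
    per-taxon treatment effects b for the taxa present in ``Y``.
    """
    path = Path(path)
    pd.DataFrame({"sample_id": Y.sample_ids, "x": draw.x.astype(int),
                  "a": draw.a}).to_csv(path, sep="\t", index=False)
    taxa_path = path.with_suffix("").with_suffix(".taxa.tsv")
    full_b = pd.Series(draw.b_vec, index=[f"taxon{j:04d}" for j in
                                          range(len(draw.b_vec))])
    b = full_b.reindex(Y.taxon_ids.astype(str))
    pd.DataFrame({"taxon_id": Y.taxon_ids, "b": b.to_numpy()}
                 ).to_csv(taxa_path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


@dataclass
class Dataset:
    """A count table aligned with per-sample metadata plus provenance."""

    counts: CountMatrix
    metadata: pd.DataFrame
    treatment_col: str = "x"
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        meta = self.metadata
        missing = set(map(str, self.counts.sample_ids)) - set(map(str, meta.index))
        if missing:
            raise ValueError(f"metadata missing samples: {sorted(missing)[:5]} ...")
        self.metadata = meta.loc[[str(s) for s in self.counts.sample_ids]]
        if self.treatment_col not in self.metadata.columns:
            raise ValueError(f"metadata lacks treatment column "
                             f"{self.treatment_col!r}")

    @property
    def treatment(self) -> np.ndarray:
        return self.metadata[self.treatment_col].to_numpy()

    def record(self, note: str) -> None:
        self.provenance.append(note)
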