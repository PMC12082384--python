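"""Read 10x-style V(D)J contig tables and CITE count matrices, and resolve
each cell barcode to a single paired alpha+beta clonotype.

A clonotype is defined by the exact combination of the alpha-chain and
beta-chain CDR3 amino-acid sequences.  Cells lacking a complete, productive
annotation for both chains are excluded from all downstream analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

#: Amino-acid alphabet accepted in a CDR3 sequence (stop codons '*' and
#: ambiguous residues disqualify the contig from clonotype calling).
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

_MANDATORY_COLUMNS = ("barcode", "chain", "cdr3", "productive", "umis")

_TRUE_STRINGS = {"true", "t", "1", "yes"}
_FALSE_STRINGS = {"false", "f", "0", "no", "none", ""}


@dataclass(frozen=True)
class ContigRecord:
    """One V(D)J contig call for one cell barcode."""

    barcode: str
    chain: str  # "TRA", "TRB", or other locus string
    cdr3_aa: str | None
    cdr3_nt: str | None
    productive: bool
    umis: int
    is_cell: bool = True
    high_confidence: bool = True


@dataclass(frozen=True)
class CellClonotype:
    """A cell resolved to its paired alpha+beta CDR3-aa clonotype."""

    barcode: str
    alpha_cdr3_aa: str
    beta_cdr3_aa: str

    @property
    def clonotype_key(self) -> str:
        return make_clonotype_key(self.alpha_cdr3_aa, self.beta_cdr3_aa)


def make_clonotype_key(alpha_cdr3_aa: str, beta_cdr3_aa: str) -> str:
    """Canonical clonotype identifier: a pure function of the two CDR3s."""
    if not alpha_cdr3_aa or not beta_cdr3_aa:
        raise ValueError("both CDR3 sequences must be non-empty")
    return f"TRA:{alpha_cdr3_aa}|TRB:{beta_cdr3_aa}"


def _parse_bool(value: object, column: str, line: int) -> bool:
    text = str(value).strip().lower()
    if text in _TRUE_STRINGS:
        return True
    if text in _FALSE_STRINGS:
        return False
    raise FormatError(
        f"line {line}: cannot parse boolean column '{column}' from {value!r}"
    )


def _parse_cdr3(value: object) -> str | None:
    text = "" if value is None else str(value).strip()
    if text == "" or text.lower() in ("none", "nan"):
        return None
    return text


def read_contigs(path: str | Path) -> list[ContigRecord]:
    """Parse a ``filtered_contig_annotations.csv``-dialect table.

    Mandatory columns: barcode, chain, cdr3, productive, umis.  Optional
    columns is_cell / high_confidence / cdr3_nt default to permissive values
    when absent.  Missing CDR3s are encoded as "None" or empty in the 10x
    dialect and become ``None`` here.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise FormatError(f"cannot parse contig table {path}: {exc}") from exc
    for column in _MANDATORY_COLUMNS:
        if column not in table.columns:
            raise FormatError(
                f"contig table {path} is missing mandatory column '{column}'"
            )
    has_nt = "cdr3_nt" in table.columns
    has_is_cell = "is_cell" in table.columns
    has_hc = "high_confidence" in table.columns

    records: list[ContigRecord] = []
    for i, row in enumerate(table.itertuples(index=False)):
        line = i + 2  # 1-based, after the header
        row = row._asdict()
        try:
            umis = int(row["umis"])
            if umis < 0:
                raise ValueError("negative UMI count")
        except ValueError as exc:
            raise FormatError(
                f"line {line}: cannot parse 'umis' from {row['umis']!r}"
            ) from exc
        records.append(
            ContigRecord(
                barcode=row["barcode"],
                chain=row["chain"],
                cdr3_aa=_parse_cdr3(row["cdr3"]),
                cdr3_nt=_parse_cdr3(row["cdr3_nt"]) if has_nt else None,
                productive=_parse_bool(row["productive"], "productive", line),
                umis=umis,
                is_cell=_parse_bool(row["is_cell"], "is_cell", line)
                if has_is_cell
                else True,
                high_confidence=_parse_bool(
                    row["high_confidence"], "high_confidence", line
                )
                if has_hc
                else True,
            )
        )
    return records


def _valid_cdr3(cdr3: str | None) -> bool:
    return cdr3 is not None and len(cdr3) > 0 and set(cdr3) <= AA_ALPHABET


def call_clonotypes(contigs: Iterable[ContigRecord]) -> list[CellClonotype]:
    """Resolve each barcode to one paired alpha+beta clonotype.

    Contigs are first filtered to cell-associated, high-confidence,
    productive calls with a valid CDR3 amino-acid sequence.  Per barcode and
    locus the contig with the highest UMI support is kept (ties broken by
    lexicographically smallest CDR3).  Barcodes lacking either a TRA or a
    TRB contig after filtering are excluded; exclusions are logged, never
    raised.  The result is independent of input order.
    """
    best: dict[str, dict[str, tuple[int, str]]] = {}
    barcodes_seen: set[str] = set()
    n_filtered = 0
    for contig in contigs:
        barcodes_seen.add(contig.barcode)
        if not (contig.is_cell and contig.high_confidence and contig.productive):
            n_filtered += 1
            continue
        if contig.chain not in ("TRA", "TRB") or not _valid_cdr3(contig.cdr3_aa):
            n_filtered += 1
            continue
        per_locus = best.setdefault(contig.barcode, {})
        # rank: more UMIs wins; ties -> lexicographically smallest CDR3
        candidate = (-contig.umis, contig.cdr3_aa)
        incumbent = per_locus.get(contig.chain)
        if incumbent is None or candidate < incumbent:
            per_locus[contig.chain] = candidate

    cells: list[CellClonotype] = []
    for barcode in sorted(best):
        per_locus = best[barcode]
        if "TRA" in per_locus and "TRB" in per_locus:
            cells.append(
                CellClonotype(
                    barcode=barcode,
                    alpha_cdr3_aa=per_locus["TRA"][1],
                    beta_cdr3_aa=per_locus["TRB"][1],
                )
            )
    n_excluded = len(barcodes_seen) - len(cells)
    logger.info(
        "call_clonotypes: %d barcodes in, %d contigs filtered, "
        "%d cells excluded for incomplete alpha/beta pairing, %d cells retained",
        len(barcodes_seen),
        n_filtered,
        n_excluded,
        len(cells),
    )
    return cells


def clonotype_frame(cells: Sequence[CellClonotype]) -> pd.DataFrame:
    """Tabular view of resolved cells (one row per retained barcode)."""
    return pd.DataFrame(
        {
            "barcode": [c.barcode for c in cells],
            "alpha_cdr3_aa": [c.alpha_cdr3_aa for c in cells],
            "beta_cdr3_aa": [c.beta_cdr3_aa for c in cells],
            "clonotype_key": [c.clonotype_key for c in cells],
        }
    )


REQUIRED_MARKERS = ("CD4", "CD8", "CD69")


def read_cite_matrix(path: str | Path) -> pd.DataFrame:
    """Read a barcode x marker antibody-count table.

    Accepts a CSV with a ``barcode`` column, or a directory holding an MTX
    triplet (``matrix.mtx`` + ``barcodes.tsv`` + ``features.tsv``).  The
    markers CD4, CD8 and CD69 must be present; counts must be non-negative
    integers.  Returns a DataFrame indexed by barcode.
    """
    path = Path(path)
    if path.is_dir():
        from scipy.io import mmread

        matrix = np.asarray(mmread(path / "matrix.mtx").todense())
        barcodes = (path / "barcodes.tsv").read_text().split()
        features = (path / "features.tsv").read_text().split()
        if matrix.shape != (len(features), len(barcodes)):
            raise FormatError(
                f"MTX shape {matrix.shape} does not match "
                f"{len(features)} features x {len(barcodes)} barcodes"
            )
        table = pd.DataFrame(matrix.T, index=barcodes, columns=features)
    else:
        table = pd.read_csv(path)
        if "barcode" not in table.columns:
            raise FormatError(f"CITE table {path} is missing column 'barcode'")
        table = table.set_index("barcode")
    for marker in REQUIRED_MARKERS:
        if marker not in table.columns:
            raise FormatError(f"CITE table {path} is missing marker '{marker}'")
    counts = table[list(REQUIRED_MARKERS)].astype(np.int64)
    if (counts.to_numpy() < 0).any():
        raise FormatError(f"CITE table {path} contains negative counts")
    return counts
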