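"""Readers and writers for the three tab-separated input dialects plus
prediction / report output.

Input formats:

* interaction file — 3 columns ``id_a<TAB>id_b<TAB>integer_score`` in the
  dialect of a STITCH ``chemical_chemical.links`` dump (optional single
  header line, transparent gzip for ``.gz`` paths);
* similarity file — same shape with a real score in [0, 1];
* label file — 2 columns ``drug_id<TAB>code1,code2,...`` with full ATC
  codes or bare level-1 letters; repeated drug lines merge by set union.

Strict parsing (the default) fails fast with the offending line number;
lenient parsing skips malformed lines and logs how many were dropped.
"""

from __future__ import annotations

import gzip
import json
import logging
import warnings
from pathlib import Path
from typing import Callable, Iterable, Sequence, TextIO

from .atc import LabelTable, atc_class_from_index, atc_level1_class, build_label_table
from .evaluation import EvaluationReport
from .predictor import RankedPrediction
from .scores import ScoreTable, build_score_table

__all__ = [
    "read_interactions",
    "read_similarities",
    "read_labels",
    "write_score_table",
    "write_labels",
    "write_predictions",
    "write_report_json",
    "write_report_tsv",
    "report_tsv_rows",
]

logger = logging.getLogger(__name__)


def _open_text(path: str | Path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def _parse_score_file(
    path: str | Path,
    parse_score: Callable[[str], float],
    check: Callable[[float], str | None],
    strict: bool,
) -> Iterable[tuple[str, str, float]]:
    """Yield (id_a, id_b, score) triples from a 3-column TSV.

    A single leading header line is tolerated when its third field does
    not parse as a number (missing-value tokens such as "NA" are treated
    as data, not headers).  ``check`` may veto a parsed score (returning a
    message) — vetoed rows raise in strict mode and are skipped otherwise.
    """
    missing_tokens = {"NA", "NAN", "NULL", "NONE", "."}
    edges: list[tuple[str, str, float]] = []
    skipped = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            problem: str | None = None
            score: float | None = None
            if len(fields) != 3:
                problem = f"expected 3 tab-separated fields, found {len(fields)}"
            else:
                try:
                    score = parse_score(fields[2].strip())
                except ValueError:
                    problem = f"unparseable score {fields[2].strip()!r}"
                else:
                    problem = check(score)
            if problem is not None:
                if (
                    lineno == 1
                    and len(fields) == 3
                    and score is None
                    and fields[2].strip().upper() not in missing_tokens
                ):
                    continue  # header line
                if strict:
                    raise ValueError(f"{path}: line {lineno}: {problem}")
                skipped += 1
                continue
            assert score is not None
            edges.append((fields[0].strip(), fields[1].strip(), score))
    if skipped:
        logger.warning("%s: skipped %d malformed line(s) in lenient mode", path, skipped)
    return edges


def read_interactions(path: str | Path, *, strict: bool = True) -> ScoreTable:
    """Read a STITCH-style interaction score file into a ScoreTable.

    Scores must be nonnegative integers; values above 1000 are kept with a
    warning (the 1..1000 range is advisory).  Duplicate pairs keep the
    larger score.
    """

    def check(v: float) -> str | None:
        if v < 0:
            return f"negative interaction score {int(v)}"
        if v > 1000:
            warnings.warn(
                f"{path}: interaction score {int(v)} above the nominal 1..1000 range",
                stacklevel=3,
            )
        return None

    edges = _parse_score_file(path, lambda s: float(int(s)), check, strict)
    table = build_score_table("interaction", edges)
    logger.info(
        "%s: loaded %d interaction pairs covering %d chemicals",
        path, table.n_pairs, len(table.covered_ids),
    )
    return table


def read_similarities(path: str | Path, *, strict: bool = True) -> ScoreTable:
    """Read a 3-column similarity score file (real scores in [0, 1])."""

    def check(v: float) -> str | None:
        if not (0 <= v <= 1):
            return f"similarity score {v} outside [0, 1]"
        return None

    edges = _parse_score_file(path, float, check, strict)
    table = build_score_table("similarity", edges)
    logger.info(
        "%s: loaded %d similarity pairs covering %d chemicals",
        path, table.n_pairs, len(table.covered_ids),
    )
    return table


def read_labels(path: str | Path, *, strict: bool = True) -> LabelTable:
    """Read a 2-column drug -> ATC-codes file into a LabelTable.

    Repeated drug-id lines merge by set union of their codes.  An empty
    code field is an error (with its line number); in lenient mode such
    lines are skipped, as are individual unparseable codes.
    """
    merged: dict[str, list[str]] = {}
    skipped = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0].strip() or not fields[1].strip():
                if strict:
                    raise ValueError(
                        f"{path}: line {lineno}: expected 'drug_id<TAB>code1,code2,...'"
                    )
                skipped += 1
                continue
            drug_id = fields[0].strip()
            codes = [c.strip() for c in fields[1].split(",") if c.strip()]
            good: list[str] = []
            for code in codes:
                try:
                    atc_level1_class(code)
                except ValueError as exc:
                    if strict:
                        raise ValueError(f"{path}: line {lineno}: {exc}") from None
                    skipped += 1
                    continue
                good.append(code)
            if good:
                merged.setdefault(drug_id, []).extend(good)
            elif strict:
                raise ValueError(f"{path}: line {lineno}: no valid ATC code")
    if skipped:
        logger.warning("%s: skipped %d malformed line(s)/code(s) in lenient mode", path, skipped)
    table = build_label_table(list(merged.items()))
    logger.info(
        "%s: loaded %d drugs (%d virtual)", path, len(table), table.virtual_count()
    )
    return table


# -- writers ---------------------------------------------------------------

def _format_score(kind: str, score: float) -> str:
    return str(int(score)) if kind == "interaction" else repr(float(score))


def write_score_table(table: ScoreTable, path: str | Path) -> None:
    """Write a score table as a 3-column TSV (sorted pairs, no header).

    Floats are written with full repr precision so that a write/read
    round-trip reproduces the table exactly.
    """
    with _open_text(path, "wt") as fh:
        for a, b, s in table.items():
            fh.write(f"{a}\t{b}\t{_format_score(table.kind, s)}\n")


def write_labels(labels: LabelTable, path: str | Path) -> None:
    """Write a label table as a 2-column TSV using bare class letters."""
    with _open_text(path, "wt") as fh:
        for drug_id in labels.drug_ids():
            letters = ",".join(
                atc_class_from_index(j).letter for j in sorted(labels[drug_id].classes)
            )
            fh.write(f"{drug_id}\t{letters}\n")


PREDICTION_COLUMNS = ("drug_id", "rank", "class_letter", "class_index", "likelihood", "method_used")


def write_predictions(predictions: Sequence[RankedPrediction], path: str | Path) -> None:
    """Write rankings as a TSV, one row per (drug, rank).

    Likelihoods are printed at full precision (raw integers for
    interaction-based rows) so rankings are auditable.
    """
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(PREDICTION_COLUMNS) + "\n")
        for pred in predictions:
            for rank, (cls, score) in enumerate(zip(pred.order, pred.scores), start=1):
                letter = atc_class_from_index(cls).letter
                val = str(int(score)) if float(score).is_integer() else repr(float(score))
                fh.write(
                    f"{pred.drug_id}\t{rank}\t{letter}\t{cls}\t{val}\t{pred.method_used}\n"
                )


def write_report_json(report: EvaluationReport, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


_TSV_METHODS = ("interaction", "similarity", "none")


def report_tsv_rows(report: EvaluationReport) -> list[dict[str, float]]:
    """Per-order accuracy rows of the report TSV.

    Each row carries the per-method accuracy contributions (hits among the
    drugs routed to that method, divided by the total N) and their sum,
    which equals the overall AC_j.
    """
    rows = []
    n = report.n_queries
    for j in range(len(report.cp)):
        row: dict[str, float] = {"order": j + 1}
        total = 0.0
        for meth in _TSV_METHODS:
            cp = report.cp_by_method.get(meth)
            val = (cp[j] / n) if cp is not None else 0.0
            row[f"ac_{meth}"] = val
            total += val
        row["ac_total"] = total
        rows.append(row)
    return rows


def write_report_tsv(report: EvaluationReport, path: str | Path) -> None:
    """Write the per-order accuracy table (one row per prediction order,
    one accuracy column per routing method plus their total)."""
    rows = report_tsv_rows(report)
    columns = ["order"] + [f"ac_{m}" for m in _TSV_METHODS] + ["ac_total"]
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write(
                "\t".join(
                    str(int(row[c])) if c == "order" else repr(row[c]) for c in columns
                )
                + "\n"
            )
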