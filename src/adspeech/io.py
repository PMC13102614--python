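"""File formats: JSONL corpora, TSV frequency tables, CSV tables, JSON reports.

All readers parse by header/field names, so column order never matters on
input; writers emit deterministic orderings so identical objects always
serialize byte-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import registry
from .annotation import AnnotatedTranscript
from .biomarkers import ReferenceFrequencyTable
from .errors import DataError, InvalidConfigError

_TOTAL_MARK = "__TOTAL__"


# ---------------------------------------------------------------------------
# transcript corpora (JSON lines)


def write_corpus(records: list[dict], path) -> None:
    """One JSON object per line: id, label, text, optional gold annotation."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            row = {"id": r["id"], "label": r["label"], "text": r["text"]}
            if "gold" in r and r["gold"] is not None:
                gold = r["gold"]
                row["gold"] = gold.to_dict() if hasattr(gold, "to_dict") else gold
            fh.write(json.dumps(row, sort_keys=True) + "\n")


def read_corpus(path) -> list[dict]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                row = json.loads(line)
            except json.JSONDecodeError as e:
                raise DataError(f"{path}: malformed JSON at line {lineno}: {e}") from e
            for key in ("id", "label", "text"):
                if key not in row:
                    raise DataError(f"{path}: line {lineno} missing field {key!r}")
            if "gold" in row and row["gold"] is not None:
                row["gold"] = AnnotatedTranscript.from_dict(row["gold"])
            records.append(row)
    return records


# ---------------------------------------------------------------------------
# reference frequency tables (TSV)


def write_frequency_tables(tables: dict, path) -> None:
    """TSV with header (register, n, gram, count) plus one total line per
    (register, n) table, rows sorted for byte-stable output."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("register\tn\tgram\tcount\n")
        for (reg, n) in sorted(tables):
            t = tables[(reg, n)]
            fh.write(f"{reg}\t{n}\t{_TOTAL_MARK}\t{t.total}\n")
            for gram in sorted(t.counts):
                fh.write(f"{reg}\t{n}\t{gram}\t{t.counts[gram]}\n")


def read_frequency_tables(path) -> dict:
    counts: dict[tuple[str, int], dict] = {}
    totals: dict[tuple[str, int], int] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            ireg, inn = header.index("register"), header.index("n")
            igram, icnt = header.index("gram"), header.index("count")
        except ValueError as e:
            raise DataError(f"{path}: missing column in header: {e}") from e
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            try:
                key = (parts[ireg], int(parts[inn]))
                gram, cnt = parts[igram], int(parts[icnt])
            except (IndexError, ValueError) as e:
                raise DataError(f"{path}: malformed row at line {lineno}") from e
            if gram == _TOTAL_MARK:
                totals[key] = cnt
            else:
                counts.setdefault(key, {})[gram] = cnt
    tables = {}
    for key, c in counts.items():
        if key not in totals:
            raise DataError(f"{path}: no total line for table {key}")
        tables[key] = ReferenceFrequencyTable(register=key[0], n=key[1],
                                              counts=c, total=totals[key])
    return tables


# ---------------------------------------------------------------------------
# feature tables (CSV)


def write_feature_table(df: pd.DataFrame, path) -> None:
    """Participant rows: id, label, then the 32 biomarker columns in
    registry order (the column-order contract of the format)."""
    cols = ["label"] + [c for c in registry.CODES if c in df.columns]
    df[cols].to_csv(path, index=True, index_label="id")


def read_feature_table(path) -> pd.DataFrame:
    """Header-name-based parse; columns are normalized to registry order."""
    df = pd.read_csv(path)
    if "id" not in df.columns:
        raise DataError(f"{path}: feature table must carry an 'id' column")
    df = df.set_index("id")
    known = [c for c in registry.CODES if c in df.columns]
    cols = (["label"] if "label" in df.columns else []) + known
    return df[cols]


def split_feature_table(df: pd.DataFrame):
    """Separate a labeled feature table into (features, labels)."""
    if "label" not in df.columns:
        raise DataError("feature table has no 'label' column")
    return df.drop(columns=["label"]), df["label"]


# ---------------------------------------------------------------------------
# JSON reports


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")


def read_json(path) -> dict:
    try:
        return json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as e:
        raise DataError(f"{path}: malformed JSON: {e}") from e


def require_exists(path, what: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise InvalidConfigError(f"{what} not found: {p}")
    return p
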