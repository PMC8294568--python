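"""Readers, writers and sample-ID parsing for SCFA and OTU tables.

Sample IDs follow the study layout ``Donor-Condition-Timepoint`` with two
timepoint-coding dialects that disagree on the meaning of token ``"02"``:

* dialect **A**: ``00`` -> 0 h, ``02`` -> 2 h, ``04`` -> 4 h (plus 06/08/24)
* dialect **B**: ``00`` -> 0 h, ``01`` -> 2 h, ``02`` -> 4 h

Because the same token means different hours in the two dialects, the
dialect is always an explicit argument (a file-level config key), never
auto-detected.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SCFAS = ("acetate", "propionate", "butyrate")
STUDY_TIMEPOINTS_H = (0.0, 2.0, 4.0, 6.0, 8.0, 24.0)


class Condition(str, enum.Enum):
    """Culture condition: a fiber spike-in or the no-spike control."""

    CONTROL = "control"
    CELLULOSE = "cellulose"
    INULIN = "inulin"
    PECTIN = "pectin"


_CONDITION_TOKENS = {
    "Ctrl": Condition.CONTROL,
    "Cell": Condition.CELLULOSE,
    "Inul": Condition.INULIN,
    "Pect": Condition.PECTIN,
}
_TOKEN_OF_CONDITION = {v: k for k, v in _CONDITION_TOKENS.items()}

# timepoint token -> hours, per dialect
_TIMEPOINT_TOKENS = {
    "A": {"00": 0.0, "02": 2.0, "04": 4.0, "06": 6.0, "08": 8.0, "24": 24.0},
    "B": {"00": 0.0, "01": 2.0, "02": 4.0},
}


class SampleIdError(ValueError):
    """A sample ID could not be parsed under the declared dialect."""


class TableFormatError(ValueError):
    """A table violates the expected layout or value constraints."""


@dataclass(frozen=True)
class SampleKey:
    """Fully resolved identity of one ex vivo sample.

    ``replicate`` indexes the biological replicate well (>= 1); it is not
    encoded in the study's sample IDs and defaults to 1 at parse time.
    """

    donor_id: str
    condition: Condition
    timepoint_h: float
    replicate: int = 1
    dialect: str = "A"

    def __post_init__(self) -> None:
        if self.timepoint_h < 0:
            raise ValueError(f"negative timepoint: {self.timepoint_h}")
        if self.replicate < 1:
            raise ValueError(f"replicate index must be >= 1, got {self.replicate}")
        if self.dialect not in _TIMEPOINT_TOKENS:
            raise ValueError(f"unknown dialect {self.dialect!r}")


@dataclass
class ScfaSeries:
    """One (donor, condition, SCFA, replicate) concentration trajectory in mM."""

    donor_id: str
    condition: Condition
    scfa: str
    replicate: int
    concentrations: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scfa not in SCFAS:
            raise ValueError(f"unknown SCFA {self.scfa!r}; expected one of {SCFAS}")
        for t, c in self.concentrations.items():
            if not np.isfinite(c) or c < 0:
                raise ValueError(
                    f"concentration at t={t} must be finite and >= 0, got {c}"
                )

    @property
    def timepoints(self) -> tuple[float, ...]:
        return tuple(sorted(self.concentrations))


@dataclass
class OtuTable:
    """Samples x OTUs integer count table with optional 7-rank taxonomy."""

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray  # (n_samples, n_otus), non-negative ints
    taxonomy: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise TableFormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise TableFormatError("OTU counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise TableFormatError("OTU counts must be non-negative")

    @property
    def depths(self) -> np.ndarray:
        """Per-sample read depth (row sums)."""
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)


def parse_sample_id(raw: str, dialect: str = "A") -> SampleKey:
    """Parse ``Donor-Condition-Timepoint`` into a :class:`SampleKey`.

    The dialect decides how the two-digit timepoint token maps to hours;
    see module docstring. Raises :class:`SampleIdError` naming the bad
    token on any unrecognized piece.
    """
    if dialect not in _TIMEPOINT_TOKENS:
        raise SampleIdError(f"unknown dialect {dialect!r} (expected 'A' or 'B')")
    m = re.fullmatch(r"([^-–]+)[-–]([^-–]+)[-–]([^-–]+)", raw.strip())
    if m is None:
        raise SampleIdError(
            f"sample ID {raw!r} does not match Donor-Condition-Timepoint"
        )
    donor, cond_tok, tp_tok = m.groups()
    if cond_tok not in _CONDITION_TOKENS:
        raise SampleIdError(f"unknown condition token {cond_tok!r} in {raw!r}")
    tp_map = _TIMEPOINT_TOKENS[dialect]
    if tp_tok not in tp_map:
        raise SampleIdError(
            f"unknown timepoint token {tp_tok!r} for dialect {dialect} in {raw!r}"
        )
    return SampleKey(
        donor_id=donor,
        condition=_CONDITION_TOKENS[cond_tok],
        timepoint_h=tp_map[tp_tok],
        dialect=dialect,
    )


def format_sample_id(key: SampleKey) -> str:
    """Inverse of :func:`parse_sample_id` for study-layout timepoints."""
    tp_map = _TIMEPOINT_TOKENS[key.dialect]
    tokens = [tok for tok, h in tp_map.items() if h == key.timepoint_h]
    if not tokens:
        raise SampleIdError(
            f"timepoint {key.timepoint_h} h has no token in dialect {key.dialect}"
        )
    return f"{key.donor_id}-{_TOKEN_OF_CONDITION[key.condition]}-{tokens[0]}"


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix in {".xlsx", ".xlsm"}:
        return pd.read_excel(path)
    sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=sep)


def read_scfa_table(path: str | Path, dialect: str = "A") -> list[ScfaSeries]:
    """Read a wide SCFA table (one row per sample ID x replicate) into series.

    Expected columns: ``sample_id``, optional ``replicate`` (defaults to 1),
    and one column per SCFA (acetate, propionate, butyrate) in mM. Returns
    3 series per distinct (sample row group); each series carries the full
    trajectory for one (donor, condition, SCFA, replicate).
    """
    df = _read_table(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    if "sample_id" not in df.columns:
        raise TableFormatError("missing required column 'sample_id'")
    missing = [s for s in SCFAS if s not in df.columns]
    if missing:
        raise TableFormatError(f"missing SCFA column(s): {missing}")
    if "replicate" not in df.columns:
        df["replicate"] = 1

    dup = df.duplicated(subset=["sample_id", "replicate"])
    if dup.any():
        rows = df.index[dup].tolist()
        raise TableFormatError(f"duplicate sample ID(s) at row(s) {rows}")

    series: dict[tuple[str, Condition, str, int], ScfaSeries] = {}
    for idx, row in df.iterrows():
        key = parse_sample_id(str(row["sample_id"]), dialect)
        rep = int(row["replicate"])
        for scfa in SCFAS:
            val = row[scfa]
            try:
                conc = float(val)
            except (TypeError, ValueError):
                raise TableFormatError(
                    f"non-numeric {scfa} value {val!r} at row {idx}"
                ) from None
            if not np.isfinite(conc):
                raise TableFormatError(f"non-finite {scfa} value at row {idx}")
            skey = (key.donor_id, key.condition, scfa, rep)
            s = series.setdefault(
                skey,
                ScfaSeries(key.donor_id, key.condition, scfa, rep),
            )
            if key.timepoint_h in s.concentrations:
                raise TableFormatError(
                    f"duplicate timepoint {key.timepoint_h} h for "
                    f"{key.donor_id}/{key.condition.value}/{scfa} rep {rep}"
                )
            s.concentrations[key.timepoint_h] = conc
    return list(series.values())


def write_scfa_table(
    series: Iterable[ScfaSeries], path: str | Path, dialect: str = "A"
) -> None:
    """Write series back to the wide study layout (inverse of the reader)."""
    rows: dict[tuple[str, int], dict[str, object]] = {}
    for s in series:
        for t, c in s.concentrations.items():
            sid = format_sample_id(
                SampleKey(s.donor_id, s.condition, t, s.replicate, dialect)
            )
            row = rows.setdefault(
                (sid, s.replicate), {"sample_id": sid, "replicate": s.replicate}
            )
            row[s.scfa] = c
    df = pd.DataFrame(list(rows.values()))
    df = df[["sample_id", "replicate", *SCFAS]]
    path = Path(path)
    sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    df.to_csv(path, sep=sep, index=False)


def read_otu_table(
    path: str | Path,
    samples_as_rows: bool = True,
    taxonomy_column: str = "taxonomy",
) -> OtuTable:
    """Read a QIIME-classic-like TSV count table.

    With ``samples_as_rows=False`` the file is transposed after loading
    (classic layout: OTUs as rows, samples as columns). A trailing
    ``taxonomy`` column/row of 7-rank lineage strings is split off if
    present.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    taxonomy: dict[str, str] | None = None
    if samples_as_rows:
        if taxonomy_column in df.index:
            taxonomy = df.loc[taxonomy_column].astype(str).to_dict()
            df = df.drop(index=taxonomy_column)
        counts = df
    else:
        if taxonomy_column in df.columns:
            taxonomy = df[taxonomy_column].astype(str).to_dict()
            df = df.drop(columns=taxonomy_column)
        counts = df.T
    values = counts.to_numpy()
    try:
        numeric = values.astype(np.float64)
    except ValueError:
        raise TableFormatError("OTU table contains non-numeric counts") from None
    if not np.allclose(numeric, np.round(numeric)):
        raise TableFormatError("OTU counts must be whole numbers")
    if (numeric < 0).any():
        raise TableFormatError("OTU counts must be non-negative")
    return OtuTable(
        sample_ids=[str(s) for s in counts.index],
        otu_ids=[str(o) for o in counts.columns],
        counts=numeric.astype(np.int64),
        taxonomy=taxonomy,
    )


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    """Write an :class:`OtuTable` as samples-as-rows TSV (+ taxonomy row)."""
    df = table.to_frame()
    if table.taxonomy is not None:
        tax_row = pd.DataFrame(
            [[table.taxonomy.get(o, "unassigned") for o in table.otu_ids]],
            index=["taxonomy"],
            columns=table.otu_ids,
        )
        df = pd.concat([df, tax_row])
    df.to_csv(path, sep="\t")
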