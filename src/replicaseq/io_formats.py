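"""Readers and writers for the pipeline's file formats.

All on-disk formats are plain text, UTF-8, tab-separated with LF line
endings:

* ``signals.tsv`` — probe sets x samples matrix of MAS5-style signals on the
  natural scale (non-negative reals); first column is the probe-set id,
  header row gives sample ids.
* ``calls.tsv``   — detection calls, same shape/ordering as the signals,
  values in {P, A, M} (Present / Absent / Marginal).
* ``samples.tsv`` — two columns ``sample_id``, ``group`` where group is one
  of CONTROL, ALC_NTC, ALC_NTO (hyphenated spellings are normalised).
* ``annotation.tsv`` — ``probe_id``, ``gene_symbol``, ``on_platform_A``.
* GMT gene-set collections — ``name<TAB>description<TAB>member...``.

Detection call "M" (marginal) is treated as not-present everywhere
downstream; readers accept it, the synthetic generator never emits it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError

log = logging.getLogger(__name__)

#: The three study arms. "Alcohol combined" is always derived as
#: ALC_NTC ∪ ALC_NTO, never stored as a label of its own.
GROUP_LABELS = ("CONTROL", "ALC_NTC", "ALC_NTO")

VALID_CALLS = frozenset({"P", "A", "M"})


def _normalise_group(label: str) -> str:
    return str(label).strip().upper().replace("-", "_").replace("/", "_")


@dataclass
class ExpressionExperiment:
    """One microarray experiment: signals, detection calls and sample groups.

    ``signal`` and ``detection`` are probe x sample DataFrames with identical
    index/columns; ``groups`` maps each sample id to a study arm.
    """

    platform_id: str
    signal: pd.DataFrame
    detection: pd.DataFrame
    groups: pd.Series

    def __post_init__(self):
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if list(self.signal.index) != list(self.detection.index) or list(
            self.signal.columns
        ) != list(self.detection.columns):
            raise FormatError(
                "signal and detection matrices disagree in shape or ordering"
            )
        if self.signal.index.duplicated().any():
            dup = self.signal.index[self.signal.index.duplicated()][0]
            raise FormatError(f"duplicate probe id {dup!r}")
        missing = [s for s in self.signal.columns if s not in self.groups.index]
        if missing:
            raise FormatError(f"samples without group assignment: {missing}")
        bad = set(self.groups.unique()) - set(GROUP_LABELS)
        if bad:
            raise FormatError(f"unknown group labels: {sorted(bad)}")
        if (self.signal.to_numpy() < 0).any():
            raise FormatError("negative signal values are not allowed")
        calls = set(np.unique(self.detection.to_numpy()))
        if not calls <= VALID_CALLS:
            raise FormatError(
                f"detection calls outside {{P,A,M}}: {sorted(calls - VALID_CALLS)}"
            )

    # -- convenience ------------------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.signal.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.signal.columns

    def samples_in(self, groups: Iterable[str]) -> list[str]:
        """Sample ids belonging to any of the given group labels."""
        wanted = {_normalise_group(g) for g in groups}
        return [s for s in self.sample_ids if self.groups[s] in wanted]

    def present_mask(self) -> pd.DataFrame:
        """Boolean probe x sample matrix: True where the call is 'P'."""
        return self.detection == "P"


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]


@dataclass
class GeneSetCollection:
    """A named collection of gene sets (a GMT file in memory)."""

    database: str  # e.g. early_development, stem_cell, custom
    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_matrix(path: Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype_backend="numpy_nullable")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse matrix: {exc}", path=path) from exc
    if df.index.duplicated().any():
        probe = df.index[df.index.duplicated()][0]
        line = int(np.where(df.index == probe)[0][1]) + 2  # header is line 1
        raise FormatError(f"duplicate probe id {probe!r}", path=path, line=line)
    return df


def read_experiment(
    signals_path,
    calls_path,
    samples_path,
    platform_id: str,
) -> ExpressionExperiment:
    """Load one experiment from its signals / calls / samples TSV files.

    Row and column alignment between the signal and call matrices is
    enforced; a shape mismatch, an unknown group label, a duplicate probe id
    or a negative signal raises :class:`FormatError` naming file and line.
    """
    signals_path, calls_path, samples_path = (
        Path(signals_path),
        Path(calls_path),
        Path(samples_path),
    )
    signal = _read_matrix(signals_path)
    try:
        signal = signal.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric signal value: {exc}", path=signals_path)
    detection = _read_matrix(calls_path).astype(str)

    if list(signal.index) != list(detection.index):
        extra = set(signal.index).symmetric_difference(detection.index)
        raise FormatError(
            f"signal and call matrices disagree on probes (e.g. {sorted(extra)[:3]})",
            path=calls_path,
        )
    if list(signal.columns) != list(detection.columns):
        raise FormatError(
            "signal and call matrices disagree on samples", path=calls_path
        )

    neg = np.argwhere(signal.to_numpy() < 0)
    if neg.size:
        r, _ = neg[0]
        raise FormatError(
            f"negative signal for probe {signal.index[r]!r}",
            path=signals_path,
            line=int(r) + 2,
        )

    samples = pd.read_csv(samples_path, sep="\t", dtype=str)
    required = {"sample_id", "group"}
    if not required <= set(samples.columns):
        raise FormatError(
            f"samples table must have columns {sorted(required)}", path=samples_path
        )
    groups = pd.Series(
        [_normalise_group(g) for g in samples["group"]],
        index=samples["sample_id"].tolist(),
    )
    bad = [g for g in groups.unique() if g not in GROUP_LABELS]
    if bad:
        line = int(np.where([_normalise_group(g) in bad for g in samples["group"]])[0][0]) + 2
        raise FormatError(f"unknown group label {bad[0]!r}", path=samples_path, line=line)

    missing = [s for s in signal.columns if s not in groups.index]
    if missing:
        raise FormatError(
            f"samples missing from samples table: {missing}", path=samples_path
        )
    return ExpressionExperiment(
        platform_id=platform_id,
        signal=signal,
        detection=detection,
        groups=groups.loc[list(signal.columns)],
    )


def read_annotation(path) -> pd.DataFrame:
    """Read a probe annotation table (probe_id, gene_symbol, on_platform_A)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "probe_id" not in df.columns or "gene_symbol" not in df.columns:
        raise FormatError(
            "annotation table needs columns probe_id, gene_symbol", path=path
        )
    if df["probe_id"].duplicated().any():
        probe = df["probe_id"][df["probe_id"].duplicated()].iloc[0]
        raise FormatError(f"duplicate probe id {probe!r}", path=path)
    df = df.set_index("probe_id")
    if "on_platform_A" in df.columns:
        df["on_platform_A"] = df["on_platform_A"].isin(("1", "true", "True", "yes"))
    return df


def read_gmt(path, database: str = "custom") -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>member[<TAB>member...]``.

    Duplicated members within a set are deduplicated with a logged warning;
    a duplicate set name or a line with fewer than three fields is a
    :class:`FormatError`.
    """
    path = Path(path)
    coll = GeneSetCollection(database=database)
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"GMT line has {len(fields)} fields, need >= 3",
                    path=path,
                    line=lineno,
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in coll.sets:
                raise FormatError(f"duplicate set name {name!r}", path=path, line=lineno)
            uniq = list(dict.fromkeys(members))
            if len(uniq) < len(members):
                log.warning(
                    "%s:%d: set %s has %d duplicated members (deduplicated)",
                    path,
                    lineno,
                    name,
                    len(members) - len(uniq),
                )
            if not uniq:
                raise FormatError(f"set {name!r} has no members", path=path, line=lineno)
            coll.sets[name] = GeneSet(name=name, description=desc, members=tuple(uniq))
    return coll


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.6f"


def write_experiment(exp: ExpressionExperiment, out_dir) -> dict[str, Path]:
    """Write signals.tsv / calls.tsv / samples.tsv for one experiment."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "signals": out / "signals.tsv",
        "calls": out / "calls.tsv",
        "samples": out / "samples.tsv",
    }
    exp.signal.to_csv(paths["signals"], sep="\t", index_label="probe_id",
                      float_format=_FLOAT_FMT, lineterminator="\n")
    exp.detection.to_csv(paths["calls"], sep="\t", index_label="probe_id",
                         lineterminator="\n")
    pd.DataFrame({"sample_id": exp.sample_ids, "group": exp.groups.values}).to_csv(
        paths["samples"], sep="\t", index=False, lineterminator="\n"
    )
    return paths


def write_annotation(annotation: pd.DataFrame, path) -> Path:
    path = Path(path)
    df = annotation.copy()
    if "on_platform_A" in df.columns:
        df["on_platform_A"] = df["on_platform_A"].map({True: "1", False: "0"})
    df.to_csv(path, sep="\t", index_label="probe_id", lineterminator="\n")
    return path


def write_gmt(collection: GeneSetCollection, path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")
    return path


def write_results_tables(results: Mapping[str, object], out_dir) -> dict[str, Path]:
    """Write the result TSVs for whichever stages are present in ``results``.

    Recognised keys: ``differential`` (DataFrame), ``replicated_genes``
    (DataFrame), ``onoff`` (DataFrame), ``gsea`` (DataFrame). Rows are
    ordered deterministically by ascending p-value, ties broken by id, so a
    rerun produces byte-identical files. Missing stages get a header-only
    file when an empty frame is supplied.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    order_keys = {
        "differential": ["p_value", "probe_id"],
        "replicated_genes": ["p_exp1", "probe_id"],
        "onoff": ["p_value", "probe_id"],
        "gsea": ["p_value", "set_name"],
    }
    for key, df in results.items():
        if key not in order_keys:
            continue
        df = pd.DataFrame(df).reset_index(drop=True)
        by = [c for c in order_keys[key] if c in df.columns]
        if by and len(df):
            df = df.sort_values(by=by, kind="mergesort")
        path = out / f"{key}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT,
                  lineterminator="\n")
        written[key] = path
    return written
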