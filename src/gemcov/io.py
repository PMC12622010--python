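"""Result-table and annotation-file I/O.

Canonical table dialect is TSV with a header row; a machine-readable
``summary.json`` accompanies every result set.  Gene sets use the standard
GMT format (set name, description, member ids, tab separated); metabolite
pathway membership is a two-column TSV (pathway_id, metabolite_id).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .util import get_logger

__all__ = [
    "write_results", "read_result_table", "read_gmt", "write_gmt",
    "read_pathway_metabolites", "write_pathway_metabolites",
]

log = get_logger("io")

_FLOAT_FORMAT = "%.10g"  # fixed format => byte-identical reruns


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path,
                  summary: dict | None = None) -> list[Path]:
    """Write each named table as ``<name>.tsv`` plus ``summary.json``.

    Output is deterministic: a fixed float format and sorted JSON keys make
    repeated runs on identical inputs byte-identical.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out} is not writable: {exc}") from exc
    written = []
    for name, df in tables.items():
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)
        log.info("wrote %s (%d rows)", path.name, len(df))
        written.append(path)
    if summary is not None:
        path = out / "summary.json"
        path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        written.append(path)
    return written


def read_result_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: one set per line, tab separated
    ``name<TAB>description<TAB>member...``."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path,
              description: str = "na") -> Path:
    path = Path(path)
    lines = [
        "\t".join([name, description] + sorted(members))
        for name, members in sorted(sets.items())
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_pathway_metabolites(path: str | Path) -> dict[str, set[str]]:
    """Read pathway -> metabolite membership from a two-column TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"pathway_id", "metabolite_id"} <= set(df.columns):
        raise ValueError(
            "pathway membership table needs columns pathway_id, metabolite_id")
    out: dict[str, set[str]] = {}
    for pw, met in zip(df["pathway_id"], df["metabolite_id"]):
        out.setdefault(pw, set()).add(met)
    return out


def write_pathway_metabolites(mapping: dict[str, set[str]],
                              path: str | Path) -> Path:
    rows = [(pw, met) for pw in sorted(mapping) for met in sorted(mapping[pw])]
    df = pd.DataFrame(rows, columns=["pathway_id", "metabolite_id"])
    df.to_csv(path, sep="\t", index=False)
    return Path(path)
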