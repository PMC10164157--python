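"""Readers and writers for the package's plain-text formats.

All tables are delimited text (TSV) with explicit headers, so every output
round-trips through its own reader and is auditable with standard tools.
FASTQ (optionally gzipped) is the only sequence format.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
import yaml

from .evaluation import GoldStandard
from .library import CombinatorialLibrary, GuideRecord, build_library, get_design
from .quantify import CountTable

GUIDE_COLUMNS = ["guide_id", "nuclease", "spacer", "gene", "gene_class", "rank", "pam_context", "position"]


def write_guide_library(library: CombinatorialLibrary, path: str | Path) -> None:
    rows = []
    for pos, guides in ((1, library.guides_pos1), (2, library.guides_pos2)):
        for g in guides:
            rows.append(
                {
                    "guide_id": g.guide_id,
                    "nuclease": g.nuclease,
                    "spacer": g.spacer,
                    "gene": g.gene,
                    "gene_class": g.gene_class,
                    "rank": "" if g.rank is None else g.rank,
                    "pam_context": g.pam_context or "",
                    "position": pos,
                }
            )
    pd.DataFrame(rows, columns=GUIDE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_guide_library(path: str | Path, design: str | None = None) -> CombinatorialLibrary:
    """Read a guide table and build the full cross-product library.

    The design name may come from a ``design`` column or the argument.
    Row-level problems (bad nuclease, non-DNA spacer, wrong spacer length)
    are collected and reported together with their row numbers.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in GUIDE_COLUMNS if c not in table.columns and c != "position"]
    if "position" not in table.columns:
        missing.append("position")
    if missing:
        raise ValueError(f"guide table {path}: missing columns {missing}")
    if design is None:
        if "design" in table.columns and len(set(table["design"])) == 1:
            design = table["design"].iloc[0]
        else:
            raise ValueError("no design given and no unambiguous 'design' column")
    errors: list[str] = []
    per_pos: dict[int, list[GuideRecord]] = {1: [], 2: []}
    for i, row in table.iterrows():
        rowno = i + 2  # header is line 1
        try:
            pos = int(row["position"])
            if pos not in (1, 2):
                raise ValueError(f"position must be 1 or 2, got {pos}")
            rank = row["rank"].strip()
            pam = row["pam_context"].strip()
            rec = GuideRecord(
                guide_id=row["guide_id"],
                nuclease=row["nuclease"],
                spacer=row["spacer"].upper(),
                gene=row["gene"],
                gene_class=row["gene_class"],
                rank=int(rank) if rank else None,
                pam_context=pam.upper() if pam else None,
            )
            per_pos[pos].append(rec)
        except (ValueError, KeyError) as exc:
            errors.append(f"row {rowno}: {exc}")
    if errors:
        raise ValueError(f"guide table {path}: {len(errors)} bad rows:\n" + "\n".join(errors))
    return build_library(per_pos[1], per_pos[2], get_design(design))


def write_count_table(table: CountTable, path: str | Path, library: CombinatorialLibrary | None = None) -> None:
    """Count table TSV: combo_id, guide_a, guide_b, then one column per sample."""
    out = table.counts.copy()
    if library is not None:
        out.insert(0, "guide_b", library.combos["guide_b"])
        out.insert(0, "guide_a", library.combos["guide_a"])
    else:
        split = out.index.to_series().str.split("__", n=1, expand=True)
        out.insert(0, "guide_b", split[1])
        out.insert(0, "guide_a", split[0])
    out.to_csv(path, sep="\t", index_label="combo_id")


def write_sample_sheet(table: CountTable, path: str | Path) -> None:
    table.samples.to_csv(path, sep="\t", index_label="sample_id")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t").set_index("sample_id")
    if "role" not in sheet.columns:
        raise ValueError(f"sample sheet {path}: missing 'role' column")
    if "replicate" not in sheet.columns:
        sheet["replicate"] = 0
    return sheet


def read_count_table(
    path: str | Path,
    sample_sheet: str | Path | pd.DataFrame | None = None,
    *,
    column_map: dict[str, str] | None = None,
) -> CountTable:
    """Read a count table written by this package or an external one.

    ``column_map`` renames external sample columns to sample_ids before the
    sample sheet is applied, which is the adapter hook for externally
    deposited raw read-count tables.  Without a sample sheet every sample is
    given the screen_end role.
    """
    frame = pd.read_csv(path, sep="\t").set_index("combo_id")
    frame = frame.drop(columns=[c for c in ("guide_a", "guide_b") if c in frame.columns])
    if column_map:
        frame = frame.rename(columns=column_map)
    if sample_sheet is None:
        samples = pd.DataFrame(
            {"role": "screen_end", "replicate": range(1, len(frame.columns) + 1)},
            index=pd.Index(frame.columns, name="sample_id"),
        )
    elif isinstance(sample_sheet, pd.DataFrame):
        samples = sample_sheet
    else:
        samples = read_sample_sheet(sample_sheet)
    frame = frame[[c for c in frame.columns if c in samples.index]]
    samples = samples.loc[list(frame.columns)]
    samples.index.name = "sample_id"
    return CountTable(frame, samples)


def write_lfc_table(lfc, path: str | Path) -> None:
    lfc.frame.to_csv(path, sep="\t", index_label="combo_id")


def write_gene_pair_table(gp, path: str | Path) -> None:
    gp.frame.to_csv(path, sep="\t")


def _open_text(path: str | Path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[str]:
    """Yield read sequences from a (possibly gzipped) FASTQ file."""
    with _open_text(path, "r") as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline()
            if not qual:
                raise ValueError(f"{path}: truncated FASTQ record at {header.strip()!r}")
            if not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"{path}: malformed FASTQ record at {header.strip()!r}")
            yield seq


def write_fastq(reads: Iterable[str], path: str | Path, prefix: str = "read") -> int:
    n = 0
    with _open_text(path, "w") as fh:
        for i, seq in enumerate(reads, 1):
            fh.write(f"@{prefix}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")
            n = i
    return n


def write_gold_standard(gold: GoldStandard, path: str | Path) -> None:
    payload = {
        "ce_positive": sorted(gold.ce_positive),
        "ts_positive": sorted(gold.ts_positive),
        "negatives": sorted(gold.negatives),
        "source": gold.source,
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_gold_standard(path: str | Path) -> GoldStandard:
    payload = yaml.safe_load(Path(path).read_text())
    return GoldStandard(
        frozenset(payload["ce_positive"]),
        frozenset(payload["ts_positive"]),
        frozenset(payload["negatives"]),
        source=payload.get("source", str(path)),
    )


def read_dependency_scores(path: str | Path) -> pd.Series:
    """Two-column gene / score delimited text -> gene-indexed Series."""
    frame = pd.read_csv(path, sep="\t")
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (gene, score)")
    gene_col, score_col = frame.columns[:2]
    return pd.Series(frame[score_col].to_numpy(dtype=float), index=frame[gene_col], name="score")
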