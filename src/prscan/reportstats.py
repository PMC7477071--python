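"""Composition reports for selected residues versus the analysis pool.

Given the residues singled out by perturbation scanning and the full pool
they were drawn from, tabulate amino-acid-type percentages and (when
per-residue secondary-structure labels are supplied) secondary-structure
class percentages, side by side.  Percentages are reported both rounded to
integers and at full precision, together with raw counts and selected/pool
enrichment ratios.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .structure_io import three_to_one

#: One-letter amino-acid category order used in the reports.
AA_CATEGORIES = list("AVLIMFGWPDERKNQTYSHC")

#: STRIDE one-letter secondary-structure codes mapped to class names.
SS_CODE_TO_CLASS = {
    "H": "alpha-helix",
    "I": "pi-helix",
    "G": "3-10 helix",
    "E": "beta-strand",
    "B": "isolated bridge",
    "b": "isolated bridge",
    "T": "turn",
    "C": "coil",
}
SS_CATEGORIES = [
    "alpha-helix", "pi-helix", "3-10 helix", "beta-strand",
    "isolated bridge", "turn", "coil",
]


def _tally(labels, categories, what: str) -> pd.Series:
    counts = pd.Series(0, index=categories, dtype=int)
    for lab in labels:
        if lab not in counts.index:
            raise ValueError(f"unknown {what} category label: {lab!r}")
        counts[lab] += 1
    return counts


def _table(selected_labels, pool_labels, categories, what: str) -> pd.DataFrame:
    sel = _tally(selected_labels, categories, what)
    pool = _tally(pool_labels, categories, what)
    df = pd.DataFrame({"selected_count": sel, "pool_count": pool})
    df["selected_pct"] = 100.0 * df["selected_count"] / max(sel.sum(), 1)
    df["pool_pct"] = 100.0 * df["pool_count"] / max(pool.sum(), 1)
    df["selected_pct_rounded"] = df["selected_pct"].round().astype(int)
    df["pool_pct_rounded"] = df["pool_pct"].round().astype(int)
    df["enrichment"] = df["selected_pct"] / df["pool_pct"].where(df["pool_pct"] > 0)
    return df


def frequency_tables(
    selected_res_names,
    pool_res_names,
    selected_ss=None,
    pool_ss=None,
) -> dict[str, pd.DataFrame]:
    """Amino-acid (and optional secondary-structure) frequency tables.

    ``selected_res_names`` / ``pool_res_names`` are three- or one-letter
    residue codes; ``selected_ss`` / ``pool_ss`` are STRIDE one-letter
    codes or class names (both optional — the secondary-structure table is
    omitted if either is absent).  Enrichment for categories empty in the
    pool is reported as NaN, never infinite.
    """
    def to_one(name: str) -> str:
        if len(name) == 1:
            return name
        one = three_to_one(name)
        return name if one == "X" else one  # keep unknown codes verbatim

    tables = {
        "amino_acid": _table(
            [to_one(r) for r in selected_res_names],
            [to_one(r) for r in pool_res_names],
            AA_CATEGORIES,
            "amino-acid",
        )
    }
    if selected_ss is not None and pool_ss is not None:
        def to_class(code: str) -> str:
            return SS_CODE_TO_CLASS.get(code, code)

        tables["secondary_structure"] = _table(
            [to_class(s) for s in selected_ss],
            [to_class(s) for s in pool_ss],
            SS_CATEGORIES,
            "secondary-structure",
        )
    return tables


def read_ss_labels(path) -> dict[tuple[str, int], str]:
    """Read per-residue secondary-structure labels from a TSV file.

    Three whitespace-separated columns: chain id, residue number, STRIDE
    one-letter code.  Lines starting with '#' are ignored.
    """
    labels: dict[tuple[str, int], str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        chain, res_seq, code = line.split()[:3]
        labels[(chain, int(res_seq))] = code
    return labels


def write_tables(tables: dict[str, pd.DataFrame], out_dir) -> list[Path]:
    """Write each frequency table as a TSV file; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in tables.items():
        p = out_dir / f"frequency_{name}.tsv"
        df.to_csv(p, sep="\t", index_label="category")
        paths.append(p)
    return paths
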