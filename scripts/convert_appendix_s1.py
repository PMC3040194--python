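#!/usr/bin/env python
"""Convert the study's supplementary species spreadsheet to the CSV layout
this package reads (columns: species, hct, habitat, clade).

The source spreadsheet has the species code in column 1 ("PDICode"), the
tree's left-to-right taxon order in column 2, and Clade / Habitat / Hct
columns (hematocrit as a percentage per unit volume blood).  Reading the
legacy binary .xls format needs the optional xlrd engine; saving the sheet
as .xlsx or .csv first also works.

Usage:  python scripts/convert_appendix_s1.py Online_Appendix_S1.xls data/Online_Appendix_S1.csv
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

COLUMN_ALIASES = {
    "species": ["pdicode", "species", "species code"],
    "hct": ["hct"],
    "habitat": ["habitat"],
    "clade": ["clade"],
}


def read_table(path: Path) -> pd.DataFrame:
    if path.suffix.lower() in {".xls", ".xlsx"}:
        return pd.read_excel(path, sheet_name=0)
    return pd.read_csv(path)


def convert(df: pd.DataFrame) -> pd.DataFrame:
    lower = {str(c).strip().lower(): c for c in df.columns}
    out = {}
    for target, aliases in COLUMN_ALIASES.items():
        source = next((lower[a] for a in aliases if a in lower), None)
        if source is None:
            raise SystemExit(
                f"cannot find a column for {target!r} among {list(df.columns)}"
            )
        out[target] = df[source]
    result = pd.DataFrame(out).dropna(subset=["species"])
    result["species"] = result["species"].astype(str).str.strip().str.replace(" ", "_")
    return result


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("source", type=Path, help="Appendix S1 spreadsheet (.xls/.xlsx/.csv)")
    parser.add_argument("dest", type=Path, help="output CSV path")
    args = parser.parse_args()
    if not args.source.is_file():
        sys.exit(f"source file not found: {args.source}")
    table = convert(read_table(args.source))
    args.dest.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.dest, index=False)
    print(f"wrote {len(table)} species rows to {args.dest}")


if __name__ == "__main__":
    main()
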