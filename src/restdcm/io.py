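"""Plain-text IO: tab-separated tables with fixed numeric formatting.

All on-disk artifacts are TSV with a header row (time in volumes, 0-based)
or JSON sidecars, so outputs are diffable and byte-stable across reruns.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

FLOAT_FMT = "%.10g"


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT,
              lineterminator="\n")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
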