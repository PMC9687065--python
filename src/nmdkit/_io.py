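"""TSV helpers: every table carries a provenance comment line and a header."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import __version__


def write_tsv(frame: pd.DataFrame, path, index: bool = True, **provenance) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tags = " ".join(f"{k}={v}" for k, v in provenance.items())
    with open(path, "w") as fh:
        fh.write(f"# nmdkit {__version__} {tags}".rstrip() + "\n")
        frame.to_csv(fh, sep="\t", index=index)


def read_tsv(path, index_col=0, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col, **kwargs)
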