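"""Reading p-value lists and writing result tables.

The input format is the one the original desktop tool consumed: a plain
text file with one p-value per line; blank lines and lines starting with
'#' are skipped.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .metatest import PValueSet

__all__ = ["read_pvalues", "write_selected", "write_table"]


def read_pvalues(path) -> PValueSet:
    """Parse a one-p-value-per-line text file into a :class:`PValueSet`."""
    values = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        text = line.strip()
        if not text or text.startswith("#"):
            continue
        try:
            values.append(float(text))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: not a p-value: {text!r}") from exc
    if not values:
        raise ValueError(f"{path}: no p-values found")
    return PValueSet(np.asarray(values))


def write_selected(path, indices, pvalues: PValueSet) -> None:
    """Selected-tests list: one (index, p-value) row per discovery."""
    df = pd.DataFrame(
        {"index": np.asarray(indices, dtype=int),
         "pvalue": pvalues.values[np.asarray(indices, dtype=int)]}
    )
    df.to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, tsv_path, html_path=None) -> None:
    """Full per-test results table as TSV and (optionally) HTML."""
    df.to_csv(tsv_path, sep="\t", index=False)
    if html_path is not None:
        df.to_html(html_path, index=False)
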