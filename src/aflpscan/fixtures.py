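"""Packaged reference tables from the continental vole AFLP selection study.

Three tables are shipped as TSV resources: per-population summaries (21
populations: sample sizes, population-specific F_ST and F_IS, variable-marker
percentage, diversity), per-primer outlier counts (21 primer combinations,
3,839 markers, 138 high-F_ST outliers), and the 73 low-F_ST outliers with
posterior odds, F_ST, marker/allele frequencies and their triage category.
A small constants table carries dataset-level counts printed only in the
running text (3,839 scored / 3,318 polymorphic / 2,054 informative markers).

Posterior odds reported as infinite (gamma = 1 at MCMC resolution) are stored
and parsed as the ``inf`` token.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .io import AflpDataError

_EXPECTED_ROWS = {"table1": 21, "table2": 22, "table3": 73}


@dataclass
class FixtureTables:
    """Parsed study tables plus the text-level marker counts."""

    table1: pd.DataFrame  # per-population summaries
    table2: pd.DataFrame  # per-primer marker and outlier counts (incl. "Total" row)
    table3: pd.DataFrame  # the 73 low-F_ST outliers
    constants: dict[str, int]

    @property
    def table2_body(self) -> pd.DataFrame:
        """Table 2 without the totals row."""
        return self.table2[self.table2["primer"] != "Total"].reset_index(drop=True)

    @property
    def n_positive_outliers(self) -> int:
        return int(self.table2_body["n_outliers"].sum())

    @property
    def n_balancing_outliers(self) -> int:
        return len(self.table3)

    @property
    def n_neutral_informative(self) -> int:
        """Informative markers left after removing all outliers (the neutral-PCA set)."""
        return (
            self.constants["informative_markers"]
            - self.n_positive_outliers
            - self.n_balancing_outliers
        )


def _resource(name: str) -> pd.DataFrame:
    with resources.files("aflpscan.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t")


def load_fixture_tables() -> FixtureTables:
    """Load and validate the packaged study tables.

    Raises :class:`AflpDataError` if any table's row count disagrees with the
    packaged expectation (a transcription would have been corrupted).
    """
    t1 = _resource("table1_populations.tsv")
    t2 = _resource("table2_primers.tsv")
    t3 = _resource("table3_low_fst_outliers.tsv")
    t3["po"] = t3["po"].astype(float)  # "inf" token -> +infinity
    consts = _resource("study_constants.tsv")
    constants = dict(zip(consts["key"], consts["value"].astype(int)))

    for name, df in (("table1", t1), ("table2", t2), ("table3", t3)):
        if len(df) != _EXPECTED_ROWS[name]:
            raise AflpDataError(
                f"{name}: expected {_EXPECTED_ROWS[name]} rows, found {len(df)}"
            )
    body = t2[t2["primer"] != "Total"]
    if int(body["n_markers"].sum()) != constants["total_markers"]:
        raise AflpDataError("table2 marker total does not match study constants")
    for _, row in body.iterrows():
        ids = str(row["outlier_ids"]).split(";")
        if len(ids) != int(row["n_outliers"]):
            raise AflpDataError(f"table2 {row['primer']}: outlier ID list length mismatch")
    return FixtureTables(table1=t1, table2=t2, table3=t3, constants=constants)
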