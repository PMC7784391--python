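"""Plain-text exchange formats.

The native table is whitespace-delimited with columns
``id sire dam sex generation litter pen y`` (missing phenotypes written as
``NA``); EBV tables and OCS reports are CSV; matrices go to coordinate
text (i, j, value); genotypes to an animals-by-markers 0/1/2 dosage
matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "write_population",
    "read_population",
    "write_ebv",
    "write_matrix_coo",
    "write_ocs_report",
    "write_dosage",
]

_COLUMNS = ["id", "sire", "dam", "sex", "generation", "litter", "pen", "y"]


def write_population(path, population) -> None:
    """Write the pedigree/phenotype table of a :class:`PopulationState`."""
    df = population.to_table()
    df.to_csv(path, sep=" ", index=False, na_rep="NA", columns=_COLUMNS)


def read_population(path) -> pd.DataFrame:
    """Read a pedigree/phenotype table back into a DataFrame."""
    df = pd.read_csv(path, sep=r"\s+", na_values="NA")
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"table lacks columns {sorted(missing)}")
    return df


def write_ebv(path, ebvset) -> None:
    """EBV table: animal, predicted direct and social effects, scheme EBV."""
    df = ebvset.data.copy()
    df["scheme"] = ebvset.scheme
    df["converged"] = ebvset.converged
    df.to_csv(path, index=False)


def write_ocs_report(path, sire_ids, ebv, result) -> None:
    """Per-candidate OCS report plus a constraint audit line.

    Columns: candidate id, EBV, optimized genome fraction, integer mating
    count.  The audit line records the coancestry bound, the achieved value
    with the integer counts, and the solver status.
    """
    df = pd.DataFrame(
        {
            "id": np.asarray(sire_ids),
            "ebv": np.asarray(ebv, dtype=float),
            "contribution": result.contributions,
            "matings": result.sire_matings,
        }
    )
    with open(path, "w") as fh:
        fh.write(
            f"# bound={result.constraint_bound:.8g} "
            f"achieved={result.constraint_value:.8g} status={result.status}\n"
        )
        df.to_csv(fh, index=False)


def write_matrix_coo(path, matrix, threshold: float = 0.0) -> None:
    """Dump a (relationship) matrix in i j value coordinate text."""
    m = np.asarray(matrix)
    with open(path, "w") as fh:
        for i in range(m.shape[0]):
            for j in range(i, m.shape[1]):
                if abs(m[i, j]) > threshold:
                    fh.write(f"{i} {j} {m[i, j]:.10g}\n")


def write_dosage(path, dosage) -> None:
    """Genotype dump: one line per animal of 0/1/2 dosages."""
    np.savetxt(path, np.asarray(dosage, dtype=int), fmt="%d")
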