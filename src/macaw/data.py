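"""Bundled reference tables.

``tetrahymena_ma_lines`` is the per-line summary of the published
*Tetrahymena thermophila* mutation-accumulation experiment that this
package's rate arithmetic is validated against: eight retained MA lines
(two anomalous lines excluded), each sequenced after ~1000 generations
(200 for M28, which was bottlenecked fewer times), with the proportion of
the 104 Mb macronuclear genome callable under the initial and final
caller parameter profiles, and the number of validated base
substitutions per line (one each in M5, M20, M25, M29 and M40).
"""

from __future__ import annotations

import pandas as pd

from .rates import DEFAULT_GENOME_SIZE, LineInputs

#: haploid macronuclear genome size of T. thermophila (bp)
TETRAHYMENA_GENOME_SIZE = DEFAULT_GENOME_SIZE

_LINES = [
    # line, coverage, generations, fitness, callable_initial, callable_final, n_mutations
    ("M5", 64.17, 1000, 0.56, 0.92, 0.88, 1),
    ("M19", 53.05, 1000, 0.64, 0.93, 0.88, 0),
    ("M20", 34.42, 1000, 0.44, 0.93, 0.88, 1),
    ("M25", 30.88, 1000, 0.57, 0.93, 0.88, 1),
    ("M28", 50.65, 200, 0.65, 0.92, 0.87, 0),
    ("M29", 31.36, 1000, 0.49, 0.93, 0.88, 1),
    ("M40", 16.84, 1000, 0.57, 0.83, 0.63, 1),
    ("M50", 106.65, 1000, 0.38, 0.93, 0.88, 0),
]


def tetrahymena_ma_lines() -> pd.DataFrame:
    """Per-line metadata of the T. thermophila MA experiment (8 retained lines)."""
    return pd.DataFrame(
        _LINES,
        columns=[
            "line", "coverage", "generations", "fitness",
            "callable_initial", "callable_final", "n_mutations",
        ],
    )


def tetrahymena_line_inputs(
    profile: str = "final", genome_size: int = TETRAHYMENA_GENOME_SIZE
) -> list[LineInputs]:
    """Rate-estimation inputs built from the bundled line table.

    Callable sites are reconstructed as callable proportion x genome
    size under the requested parameter ``profile`` ("initial" or
    "final").
    """
    df = tetrahymena_ma_lines()
    col = {"initial": "callable_initial", "final": "callable_final"}[profile]
    return [
        LineInputs(
            line=row["line"],
            n=int(row["n_mutations"]),
            L=float(row[col]) * genome_size,
            T=float(row["generations"]),
        )
        for _, row in df.iterrows()
    ]
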