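"""Published replicate-aggregation rows used as worked examples.

These are the reported per-replicate percentages (three 1 μs MD replicates
MD1–MD3 and their "All" average) from the nucleosome abasic-site study this
package emulates: extrahelicity per lesion type and site, and residence
frequencies of H2A charged amino groups within 6 Å of the damaged sites.
They serve a single purpose here: validating the equal-weight
round-half-away-from-zero aggregation convention (``selfcheck``) and the
package's aggregation arithmetic in tests.  They are reported numbers, not
values this package can recompute from trajectories.

One row, K13(H2A)-THF7, prints an "All" value (12.8) inconsistent with the
mean of its replicate values (1.8/6.2/6.6 -> 4.9) under every aggregation
convention that fits the other rows; it is retained for completeness but
flagged and excluded from consistency checks.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ReferenceRow:
    label: str
    all_value: float
    per_replicate: tuple[float, float, float]   # MD1, MD2, MD3
    consistent: bool = True


EXTRAHELICITY_ROWS: tuple[ReferenceRow, ...] = (
    ReferenceRow("AP (Site 1)", 19.0, (14.4, 12.8, 29.7)),
    ReferenceRow("AP (Site 2)", 88.2, (67.0, 99.6, 97.9)),
    ReferenceRow("THF (Site 1)", 5.3, (3.5, 1.0, 11.5)),
    ReferenceRow("THF (Site 2)", 85.3, (56.6, 99.5, 99.7)),
)

CONTACT_ROWS: tuple[ReferenceRow, ...] = (
    ReferenceRow("K13(H2A)-AP7", 6.0, (4.5, 6.1, 7.5)),
    ReferenceRow("K13(H2A)-AP20", 9.2, (8.3, 7.9, 11.3)),
    ReferenceRow("A12(H2A)-AP20", 19.9, (5.0, 30.0, 24.8)),
    ReferenceRow("K13(H2A)-THF7", 12.8, (1.8, 6.2, 6.6), consistent=False),
    ReferenceRow("K13(H2A)-THF20", 12.2, (4.8, 14.5, 17.4)),
    ReferenceRow("A12(H2A)-THF20", 7.3, (3.2, 10.6, 8.2)),
)

ALL_ROWS: tuple[ReferenceRow, ...] = EXTRAHELICITY_ROWS + CONTACT_ROWS
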