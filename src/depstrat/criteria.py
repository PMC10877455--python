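"""The six operational lifetime-depression criteria and their encoding.

The fixed criterion order is used everywhere: bit ``i`` of a constellation id
refers to ``CRITERIA[i]``, with bit 0 the least significant bit. A
constellation id is therefore an integer in 1..63 whose popcount equals the
number of criteria met (``k``).
"""

from __future__ import annotations

#: Canonical criterion order (short column-name form).
CRITERIA = (
    "helpseek",   # help seeking for depression
    "selfrep",    # self-reported depression
    "antidep",    # antidepressant use
    "smith",      # Smith et al. depression definition
    "icd10",      # hospital ICD-10 F32/F33 diagnosis codes
    "cidisf",     # CIDI Short Form score
)

#: Human-readable labels, same order.
CRITERIA_LABELS = (
    "Help seeking",
    "Self-reported depression",
    "Antidepressant use",
    "Smith definition",
    "ICD-10 F32/F33",
    "CIDI-SF",
)

N_CRITERIA = len(CRITERIA)

#: Subject-table column names for the criteria bits.
CRITERIA_COLUMNS = tuple(f"crit_{c}" for c in CRITERIA)


def constellation_id(bits) -> int:
    """Encode a boolean criteria vector as an integer id (bit i = criterion i)."""
    return int(sum((1 << i) for i, b in enumerate(bits) if b))


def constellation_bits(cid: int, n_criteria: int = N_CRITERIA) -> tuple[bool, ...]:
    """Decode a constellation id back into its boolean criteria vector."""
    if not 0 < cid < (1 << n_criteria):
        raise ValueError(f"constellation id {cid} out of range for {n_criteria} criteria")
    return tuple(bool((cid >> i) & 1) for i in range(n_criteria))


def popcount(cid: int) -> int:
    return int(cid).bit_count()


def constellation_label(cid: int) -> str:
    """Compact label like 'antidep+icd10' for a constellation id."""
    return "+".join(c for i, c in enumerate(CRITERIA) if (cid >> i) & 1)
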