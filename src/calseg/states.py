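"""The five-state alphabet for contraceptive calendar sequences.

Each month of a woman's calendar is classified into one of five mutually
exclusive states: no use of contraception, use of a short-term modern
method, use of a long-acting or permanent method (LAPM), use of a
traditional method, or pregnancy (including birth and termination).
States are stored as small integer codes; single-letter labels are used
in delimited text files.
"""

from __future__ import annotations

import numpy as np

NONE = 0  # no contraceptive use, not pregnant
STM = 1   # short-term modern: pill, injectable, condom, LAM, EC, SDM, ...
LAPM = 2  # long-acting / permanent: IUD, implant, sterilization
TRAD = 3  # traditional: rhythm, withdrawal, other traditional
PREG = 4  # pregnancy, birth, or termination
MISSING = -1

N_STATES = 5
STATE_NAMES = ("NONE", "STM", "LAPM", "TRAD", "PREG")
STATE_LETTERS = "NSLTP"

LETTER_TO_STATE = {let: i for i, let in enumerate(STATE_LETTERS)}

#: Length of the analysis window, in months.
SEQ_LENGTH = 59


def states_to_letters(states: np.ndarray) -> str:
    """Render an integer state vector as its single-letter string form."""
    return "".join(STATE_LETTERS[s] for s in states)


def letters_to_states(letters: str) -> np.ndarray:
    """Parse a single-letter state string back to an integer vector."""
    try:
        return np.array([LETTER_TO_STATE[c] for c in letters], dtype=np.int8)
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"unknown state letter {exc.args[0]!r}") from None
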