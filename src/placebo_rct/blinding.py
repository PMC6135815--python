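"""Triple-blinding via scrambled group codes.

All group-contingent analyses can be run under three candidate labelings
("codes"), only one of which is the true classification; the other two
are cell-scrambled decoys — random permutations of the real label vector,
so every decoy preserves the exact group sizes.  The index of the real
code is sealed in a checksummed key that is only read back at the
unblinding step, after the analyses are frozen.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CODE_NAMES = ("code_A", "code_B", "code_C")


def _checksum(codes: pd.DataFrame, real_index: int, seed: int) -> str:
    payload = codes.to_csv(index=True) + f"|{real_index}|{seed}"
    return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class BlindingKey:
    """Three labelings in randomized order plus the sealed real index."""

    codes: pd.DataFrame  # index: subject_id; columns: code_A, code_B, code_C
    _sealed_index: int
    seed: int
    checksum: str

    def labeling(self, name: str) -> pd.Series:
        return self.codes[name]


def make_scrambled_codes(
    labels: pd.Series, n_decoys: int = 2, seed: int = 0
) -> BlindingKey:
    """Build the blinding key from the true labels.

    Decoys are uniform random permutations of the label vector (exact
    class counts preserved).  The real code's position among the three is
    itself randomized, then sealed.
    """
    lab = pd.Series(labels).astype(str)
    if lab.nunique() < 2:
        raise ValueError("labels must contain at least 2 distinct classes")
    rng = np.random.default_rng(seed)
    columns = [lab.to_numpy().copy()]
    for _ in range(n_decoys):
        columns.append(rng.permutation(lab.to_numpy()))
    order = rng.permutation(len(columns))
    real_index = int(np.flatnonzero(order == 0)[0])
    arranged = [columns[k] for k in order]
    codes = pd.DataFrame(
        {name: col for name, col in zip(CODE_NAMES, arranged)}, index=lab.index
    )
    codes.index.name = "subject_id"
    return BlindingKey(
        codes=codes,
        _sealed_index=real_index,
        seed=seed,
        checksum=_checksum(codes, real_index, seed),
    )


def reveal(key: BlindingKey) -> int:
    """Unseal the key: return the index of the real labeling (idempotent)."""
    if key.checksum != _checksum(key.codes, key._sealed_index, key.seed):
        raise ValueError("blinding key checksum mismatch (tampered key)")
    logger.info("UNBLINDING: real code is %s", CODE_NAMES[key._sealed_index])
    return key._sealed_index


def write_key(key: BlindingKey, codes_path: str | Path, key_path: str | Path) -> None:
    key.codes.to_csv(codes_path)
    Path(key_path).write_text(
        json.dumps(
            {"sealed_index": key._sealed_index, "seed": key.seed,
             "checksum": key.checksum},
            indent=2,
        )
    )


def read_key(codes_path: str | Path, key_path: str | Path) -> BlindingKey:
    codes = pd.read_csv(codes_path, index_col="subject_id")
    meta = json.loads(Path(key_path).read_text())
    return BlindingKey(
        codes=codes,
        _sealed_index=int(meta["sealed_index"]),
        seed=int(meta["seed"]),
        checksum=str(meta["checksum"]),
    )
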