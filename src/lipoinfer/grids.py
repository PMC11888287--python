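"""Fixed FSIGT sampling grids.

An FSIGT protocol injects glucose at t = 0 and an insulin bolus at t = 20 min,
with blood drawn at 28 fixed times over 180 minutes.  The three-state model is
integrated only on the post-bolus portion of the grid (t > 20, starting at 22),
while the two-state FFA model uses the full grid.
"""

from __future__ import annotations

import numpy as np

#: The 28 blood-sampling times (minutes post glucose injection).
T_ALL = np.array(
    [0, 2, 3, 4, 5, 6, 8, 10, 12, 14, 16, 19, 22, 24, 25, 27, 30,
     40, 50, 60, 70, 80, 90, 100, 120, 140, 160, 180],
    dtype=float,
)

#: The 16 sampling times after the insulin bolus (t > 20).
T_POST20 = T_ALL[T_ALL > 20]

assert T_ALL.shape == (28,) and T_POST20.shape == (16,)
T_ALL.setflags(write=False)
T_POST20.setflags(write=False)


def grid_for_model(model_id: str) -> np.ndarray:
    """Integration grid used by a model: ``"3d"`` -> post-20, ``"2d"`` -> full."""
    if model_id == "3d":
        return T_POST20
    if model_id == "2d":
        return T_ALL
    raise ValueError(f"unknown model_id {model_id!r}; expected '3d' or '2d'")
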