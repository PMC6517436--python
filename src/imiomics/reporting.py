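"""Figure export for correlation maps.

Orthogonal slices with a fixed diverging colour scale: r = -1 maps to blue,
0 to white, +1 to dark red (endpoints fixed at +/-1 rather than data-scaled,
matching the fixed interpretation of a correlation coefficient).  Undefined
voxels (zero imaging variance, e.g. air) are rendered grey.
"""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .errors import ValidationError  # noqa: E402
from .stats import CorrelationMap  # noqa: E402

_PLANE_AXIS = {"sagittal": 0, "coronal": 1, "axial": 2}


def export_slice(cmap: CorrelationMap, plane: str, index: int, out_path) -> None:
    """Write one slice of a correlation map as a PNG."""
    if plane not in _PLANE_AXIS:
        raise ValidationError(f"plane must be one of {sorted(_PLANE_AXIS)}")
    axis = _PLANE_AXIS[plane]
    if not 0 <= index < cmap.grid.dims[axis]:
        raise ValidationError(
            f"slice index {index} out of range for axis {axis} with "
            f"{cmap.grid.dims[axis]} voxels"
        )
    sl = np.take(cmap.r, index, axis=axis)
    data = np.ma.masked_invalid(sl.T[::-1])  # head up for coronal/sagittal
    palette = plt.get_cmap("RdBu_r").copy()
    palette.set_bad("0.5")
    plt.imsave(str(out_path), data, cmap=palette, vmin=-1.0, vmax=1.0)
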