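"""Core image container shared by the simulator and the quantification code."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Maximum representable intensity at 16-bit depth.
MAX_INTENSITY_16BIT = 2**16 - 1


@dataclass
class Micrograph:
    """A two- (or three-) channel 2D fluorescence micrograph.

    Parameters
    ----------
    green, red
        GFP and mCherry intensity grids of identical shape. Under the
        mito-QC reporter the mitochondrial network is bright in both;
        mitolysosomes are red-only (GFP quenched at lysosomal pH).
    label
        Optional cell-population marker channel (e.g. Pacific Blue
        immunolabel), same shape as the reporter channels.
    pixel_size_um
        Edge length of one pixel in micrometres; must be positive.
    bit_depth
        Bit depth of the acquisition; intensities must lie in
        ``[0, 2**bit_depth - 1]``.
    image_id
        Free-text identifier used in output tables and error messages.
    """

    green: np.ndarray
    red: np.ndarray
    label: np.ndarray | None = None
    pixel_size_um: float = 0.1
    bit_depth: int = 16
    image_id: str = ""

    def __post_init__(self) -> None:
        self.green = np.asarray(self.green)
        self.red = np.asarray(self.red)
        if self.label is not None:
            self.label = np.asarray(self.label)
        if self.green.ndim != 2:
            raise ValueError("channels must be 2D intensity grids")
        if self.red.shape != self.green.shape:
            raise ValueError(
                f"channel shape mismatch: green {self.green.shape} vs red {self.red.shape}"
            )
        if self.label is not None and self.label.shape != self.green.shape:
            raise ValueError(
                f"channel shape mismatch: green {self.green.shape} vs label {self.label.shape}"
            )
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        limit = 2**self.bit_depth - 1
        for name, chan in self.channels().items():
            if chan.size and (chan.min() < 0 or chan.max() > limit):
                raise ValueError(
                    f"{name} channel intensities outside [0, {limit}] for bit depth "
                    f"{self.bit_depth}"
                )

    def channels(self) -> dict[str, np.ndarray]:
        """Mapping of channel name to grid, in canonical order green, red, label."""
        out = {"green": self.green, "red": self.red}
        if self.label is not None:
            out["label"] = self.label
        return out

    @property
    def shape(self) -> tuple[int, int]:
        return self.green.shape

    def pixel_area_um2(self) -> float:
        return self.pixel_size_um**2
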