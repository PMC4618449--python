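"""Multi-channel 3D stack container with physical voxel calibration.

Intravital bone-marrow stacks are acquired as z-series of 2D frames with
in-plane pixel sizes well below the z step (typically 0.4-1.2 um/px in x/y
against 1-5 um between slices), so the voxel grid is anisotropic.  All
geometry downstream works in pixel units on a fixed ``(z, y, x)`` axis
order and converts to micrometers only at reporting time.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "VoxelSpacing",
    "ChannelRole",
    "VolumeStack",
    "read_stack",
    "write_stack",
    "write_label_mask",
    "read_label_mask",
    "read_sidecar",
    "write_sidecar",
]


@dataclass(frozen=True)
class VoxelSpacing:
    """Physical voxel calibration in micrometers.

    Attributes
    ----------
    dx, dy : float
        Micrometers per pixel in x and y.  The anisotropic distance
        formula assumes ``dx == dy``; readers may construct mildly
        anisotropic spacings but distance conversion will refuse them.
    sd : float
        Micrometers between consecutive z slices (the acquisition step
        size; one slice corresponds to one voxel in z).
    """

    dx: float
    dy: float
    sd: float

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dy > 0 and self.sd > 0):
            raise ValueError(
                f"voxel spacing must be strictly positive, got "
                f"dx={self.dx}, dy={self.dy}, sd={self.sd}"
            )

    @property
    def z_factor(self) -> float:
        """z-step expressed in x/y pixel units (``sd`` of the distance
        formula): micrometers per slice divided by micrometers per pixel."""
        return self.sd / self.dx

    @property
    def voxel_volume_um3(self) -> float:
        return self.dx * self.dy * self.sd


class ChannelRole(str, enum.Enum):
    """Biological identity of an acquisition channel.

    DID marks dye-labeled transplanted cells, OSTEOBLAST the GFP reporter
    signal of bone-lining cells, BONE the second-harmonic collagen signal.
    The remaining roles cover the other niche components the same
    machinery segments (vasculature, nestin+ stromal cells, macrophages).
    """

    DID = "did"
    OSTEOBLAST = "osteoblast"
    BONE = "bone"
    VESSEL = "vessel"
    NESTIN = "nestin"
    MACROPHAGE = "macrophage"
    GENERIC = "generic"


@dataclass
class VolumeStack:
    """A calibrated multi-channel 3D image.

    ``data`` has shape ``(n_channels, n_slices, height, width)``; the
    channel at index ``i`` plays the role ``channels[i]``.  Intensities
    are non-negative; 8-bit data is typical but higher bit depths pass
    through unchanged.
    """

    data: np.ndarray
    spacing: VoxelSpacing
    channels: list[ChannelRole] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"stack data must be (channel, z, y, x), got shape {self.data.shape}"
            )
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"{self.data.shape[0]} channels in data but "
                f"{len(self.channels)} channel roles declared"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel roles must be unique within a stack")
        if self.data.size and self.data.min() < 0:
            raise ValueError("intensities must be non-negative")
        if self.n_slices < 1:
            raise ValueError("stack needs at least one slice")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_slices(self) -> int:
        return self.data.shape[1]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def channel_index(self, role: ChannelRole) -> int:
        try:
            return self.channels.index(role)
        except ValueError:
            raise KeyError(f"channel role {role!r} not present in stack") from None

    def channel(self, role: ChannelRole) -> np.ndarray:
        """Return the ``(z, y, x)`` volume for one channel role."""
        return self.data[self.channel_index(role)]

    def has_channel(self, role: ChannelRole) -> bool:
        return role in self.channels


def _ome_spacing(path: Path) -> VoxelSpacing | None:
    """Extract physical spacing from OME-XML metadata if present."""
    try:
        with tifffile.TiffFile(path) as tf:
            ome = tf.ome_metadata
        if not ome:
            return None
        import xml.etree.ElementTree as ET

        root = ET.fromstring(ome)
        for el in root.iter():
            if el.tag.endswith("Pixels"):
                dx = el.get("PhysicalSizeX")
                dy = el.get("PhysicalSizeY")
                sd = el.get("PhysicalSizeZ")
                if dx and dy and sd:
                    return VoxelSpacing(float(dx), float(dy), float(sd))
        return None
    except Exception:  # malformed metadata is not fatal
        return None


def read_stack(
    path: str | Path,
    channel_roles: list[ChannelRole],
    spacing: VoxelSpacing | None = None,
) -> VolumeStack:
    """Load a TIFF/OME-TIFF stack and attach calibration and channel roles.

    Accepted on-disk layouts: ``(y, x)``, ``(z, y, x)`` single channel, or
    ``(z, c, y, x)`` multi-channel (the ImageJ hyperstack convention).
    Spacing found in OME metadata overrides the ``spacing`` argument with
    a logged notice; otherwise ``spacing`` is required.
    """
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None, None, :, :]  # (c=1, z=1, y, x)
    elif arr.ndim == 3:
        arr = arr[None, :, :, :]  # single channel z-stack
    elif arr.ndim == 4:
        arr = np.moveaxis(arr, 1, 0)  # (z, c, y, x) -> (c, z, y, x)
    else:
        raise ValueError(f"cannot interpret TIFF with {arr.ndim} axes as a stack")

    meta_spacing = _ome_spacing(path)
    if meta_spacing is not None:
        if spacing is not None and meta_spacing != spacing:
            logger.info(
                "OME metadata spacing %s overrides supplied spacing %s",
                meta_spacing,
                spacing,
            )
        spacing = meta_spacing
    if spacing is None:
        raise ValueError(
            f"{path}: no spacing in metadata; supply VoxelSpacing explicitly"
        )
    return VolumeStack(arr, spacing, list(channel_roles))


def write_stack(stack: VolumeStack, path: str | Path) -> Path:
    """Write a stack as OME-TIFF with physical spacing in the metadata."""
    path = Path(path)
    data = np.moveaxis(stack.data, 0, 1)  # (z, c, y, x)
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "ZCYX",
            "PhysicalSizeX": stack.spacing.dx,
            "PhysicalSizeY": stack.spacing.dy,
            "PhysicalSizeZ": stack.spacing.sd,
        },
    )
    return path


def write_label_mask(
    labels: np.ndarray, spacing: VoxelSpacing, path: str | Path
) -> Path:
    """Write an integer label volume as a TIFF that round-trips losslessly.

    16-bit by default; escalates to 32-bit with a notice when more than
    65535 labels are present.  Label 0 is background.
    """
    labels = np.asarray(labels)
    if labels.size and labels.min() < 0:
        raise ValueError("labels must be non-negative")
    maxlab = int(labels.max()) if labels.size else 0
    if maxlab > np.iinfo(np.uint16).max:
        logger.info("label count %d exceeds 16-bit range; writing 32-bit", maxlab)
        out = labels.astype(np.uint32)
    else:
        out = labels.astype(np.uint16)
    path = Path(path)
    tifffile.imwrite(path, out, photometric="minisblack")
    write_sidecar(path.with_suffix(path.suffix + ".json"), spacing, [])
    return path


def read_label_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path))


def write_sidecar(
    path: str | Path, spacing: VoxelSpacing, channels: list[ChannelRole]
) -> Path:
    """JSON sidecar recording spacing and channel roles for plain TIFFs."""
    path = Path(path)
    payload = {
        "spacing_um": {"dx": spacing.dx, "dy": spacing.dy, "sd": spacing.sd},
        "channels": [c.value for c in channels],
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_sidecar(path: str | Path) -> tuple[VoxelSpacing, list[ChannelRole]]:
    payload = json.loads(Path(path).read_text())
    sp = payload["spacing_um"]
    spacing = VoxelSpacing(sp["dx"], sp["dy"], sp["sd"])
    channels = [ChannelRole(c) for c in payload.get("channels", [])]
    return spacing, channels
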