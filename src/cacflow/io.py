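"""HDF5 container for channel-data ensembles and color flow outputs.

Layout (version 1.0):

    /channel_data        complex, (axial, lateral, channel, slow_time, frame)
    /grid/axial_mm       1-D pixel-center coordinates
    /grid/lateral_mm
    /provenance/scene_yaml   optional scene description
    attrs: f0, prf, c, n_channels, ensemble, frame_rate, n_frames,
           seed (optional), cacf_container_version
"""

from __future__ import annotations

import h5py

from .core import AcquisitionParams, ChannelEnsemble, PixelGrid

__all__ = ["CONTAINER_VERSION", "ContainerFormatError",
           "write_channel_container", "read_channel_container",
           "write_image", "read_image"]

CONTAINER_VERSION = "1.0"

_ACQ_ATTRS = ("f0", "prf", "c", "n_channels", "ensemble", "frame_rate", "n_frames")


class ContainerFormatError(ValueError):
    """A file does not conform to the channel-data container schema."""


def write_channel_container(path, dataset: ChannelEnsemble,
                            scene_yaml: str | None = None,
                            seed: int | None = None) -> None:
    """Write a channel-data ensemble (plus provenance) to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["cacf_container_version"] = CONTAINER_VERSION
        for name in _ACQ_ATTRS:
            f.attrs[name] = getattr(dataset.acq, name)
        f.create_dataset("channel_data", data=dataset.data)
        g = f.create_group("grid")
        g.create_dataset("axial_mm", data=dataset.grid.axial_mm)
        g.create_dataset("lateral_mm", data=dataset.grid.lateral_mm)
        prov = f.create_group("provenance")
        if scene_yaml is not None:
            prov.create_dataset("scene_yaml", data=scene_yaml)
        if seed is not None:
            f.attrs["seed"] = int(seed)


def read_channel_container(path) -> tuple[ChannelEnsemble, dict]:
    """Read a container; returns the ensemble and a provenance dict
    (``scene_yaml``, ``seed`` when present).

    Raises :class:`ContainerFormatError` naming the missing field on a
    schema mismatch, including an unknown version.
    """
    with h5py.File(path, "r") as f:
        version = f.attrs.get("cacf_container_version")
        if version is None:
            raise ContainerFormatError("missing attribute 'cacf_container_version'")
        if str(version).split(".")[0] != CONTAINER_VERSION.split(".")[0]:
            raise ContainerFormatError(
                f"unsupported container version {version!r} (supported: {CONTAINER_VERSION})")
        acq_kwargs = {}
        for name in _ACQ_ATTRS:
            if name not in f.attrs:
                raise ContainerFormatError(f"missing attribute {name!r}")
            val = f.attrs[name]
            acq_kwargs[name] = int(val) if name in ("n_channels", "ensemble", "n_frames") \
                else float(val)
        for ds in ("channel_data", "grid/axial_mm", "grid/lateral_mm"):
            if ds not in f:
                raise ContainerFormatError(f"missing dataset {ds!r}")
        acq = AcquisitionParams(**acq_kwargs)
        grid = PixelGrid(axial_mm=f["grid/axial_mm"][()],
                         lateral_mm=f["grid/lateral_mm"][()])
        ens = ChannelEnsemble(data=f["channel_data"][()], grid=grid, acq=acq)
        prov: dict = {}
        if "provenance/scene_yaml" in f:
            raw = f["provenance/scene_yaml"][()]
            prov["scene_yaml"] = raw.decode() if isinstance(raw, bytes) else str(raw)
        if "seed" in f.attrs:
            prov["seed"] = int(f.attrs["seed"])
    return ens, prov


def write_image(path, image, provenance: dict | None = None) -> None:
    """Write a :class:`~cacflow.cacf.ColorFlowImage` (velocity, selection
    index, max-SLSC, rejection mask as parallel grids) to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["cacf_container_version"] = CONTAINER_VERSION
        for name in _ACQ_ATTRS:
            f.attrs[name] = getattr(image.acq, name)
        f.create_dataset("velocity_cm_s", data=image.velocity.v_hat)
        f.create_dataset("phase_rad", data=image.velocity.phi_hat)
        f.create_dataset("rejected", data=image.rejected)
        g = f.create_group("grid")
        g.create_dataset("axial_mm", data=image.grid.axial_mm)
        g.create_dataset("lateral_mm", data=image.grid.lateral_mm)
        if image.selection is not None:
            s = f.create_group("selection")
            s.create_dataset("index", data=image.selection.index)
            s.create_dataset("cutoff_fraction", data=image.selection.cutoff_fraction)
            s.create_dataset("max_slsc", data=image.selection.max_slsc)
        for key, val in (provenance or {}).items():
            f.attrs[f"provenance_{key}"] = val


def read_image(path):
    """Read a color flow image written by :func:`write_image`."""
    from .cacf import ColorFlowImage, SelectionMap
    from .velocity import VelocityMap

    with h5py.File(path, "r") as f:
        if "cacf_container_version" not in f.attrs:
            raise ContainerFormatError("missing attribute 'cacf_container_version'")
        acq_kwargs = {
            name: (int(f.attrs[name]) if name in ("n_channels", "ensemble", "n_frames")
                   else float(f.attrs[name]))
            for name in _ACQ_ATTRS}
        acq = AcquisitionParams(**acq_kwargs)
        grid = PixelGrid(axial_mm=f["grid/axial_mm"][()],
                         lateral_mm=f["grid/lateral_mm"][()])
        vmap = VelocityMap(v_hat=f["velocity_cm_s"][()], phi_hat=f["phase_rad"][()],
                           grid=grid, acq=acq, rejected=f["rejected"][()].astype(bool))
        selection = None
        if "selection" in f:
            selection = SelectionMap(index=f["selection/index"][()],
                                     cutoff_fraction=f["selection/cutoff_fraction"][()],
                                     max_slsc=f["selection/max_slsc"][()])
        return ColorFlowImage(velocity=vmap, selection=selection, grid=grid, acq=acq)
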