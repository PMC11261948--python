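"""Readers and writers for the formats the pipeline touches.

Recordings travel as EDF (16-bit European Data Format), event tables and
channel/subject metadata as UTF-8 TSV with '.' decimal separators, event
image stores as HDF5, and trained classifiers as a single-file HDF5 bundle.
All I/O here is pure: repeated reads of the same file return equal objects.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "EVENT_COLUMNS",
    "read_recording",
    "write_edf",
    "read_event_table",
    "write_event_table",
    "empty_event_table",
    "read_channel_metadata",
    "read_subject_metadata",
    "write_image_store",
    "read_image_store",
    "save_bundle",
    "load_bundle",
    "BundleError",
]

BUNDLE_VERSION = 1

#: Required columns of an event table, in serialization order.
EVENT_COLUMNS = ["subject", "channel", "start_s", "end_s", "detector", "tags"]


class BundleError(RuntimeError):
    """Raised when a classifier bundle is unreadable or incompatible."""


@dataclass
class Recording:
    """Multichannel iEEG signal in microvolts.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling frequency in Hz.
    ch_names : list of str
        Unique channel names, row order matching ``data``.
    montage : str
        One of ``raw``, ``CAR``, ``bipolar``.
    """

    data: np.ndarray
    fs: float
    ch_names: list[str] = field(default_factory=list)
    montage: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        if not self.ch_names:
            self.ch_names = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("channel name count does not match signal rows")
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel names must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.ch_names.index(name)]

    def copy_with(self, **kwargs) -> "Recording":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: Recording, path) -> None:
    """Write a Recording as a plain 16-bit EDF file.

    The signal is padded with zeros to a whole number of 1-second data
    records. Physical units are microvolts; digital range is the full
    16-bit span per channel.
    """
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch = recording.n_channels
    n_rec = int(np.ceil(recording.n_samples / fs))
    data = np.zeros((n_ch, n_rec * fs))
    data[:, : recording.n_samples] = recording.data

    phys_min = np.floor(data.min(axis=1) - 1.0)
    phys_max = np.ceil(data.max(axis=1) + 1.0)
    dig_min, dig_max = -32768, 32767

    header = b""
    header += _edf_field("0", 8)
    header += _edf_field("X X X X", 80)
    header += _edf_field("Startdate X X X X", 80)
    header += _edf_field("01.01.00", 8)
    header += _edf_field("00.00.00", 8)
    header += _edf_field(256 * (1 + n_ch), 8)
    header += _edf_field("", 44)
    header += _edf_field(n_rec, 8)
    header += _edf_field(1, 8)
    header += _edf_field(n_ch, 4)
    for name in recording.ch_names:
        header += _edf_field(name, 16)
    header += b"".join(_edf_field("", 80) for _ in range(n_ch))
    header += b"".join(_edf_field("uV", 8) for _ in range(n_ch))
    header += b"".join(_edf_field(f"{phys_min[i]:.0f}", 8) for i in range(n_ch))
    header += b"".join(_edf_field(f"{phys_max[i]:.0f}", 8) for i in range(n_ch))
    header += b"".join(_edf_field(dig_min, 8) for _ in range(n_ch))
    header += b"".join(_edf_field(dig_max, 8) for _ in range(n_ch))
    header += b"".join(_edf_field("", 80) for _ in range(n_ch))
    header += b"".join(_edf_field(fs, 8) for _ in range(n_ch))
    header += b"".join(_edf_field("", 32) for _ in range(n_ch))

    scale = (phys_max - phys_min) / (dig_max - dig_min)
    offset = phys_max - scale * dig_max
    digital = np.round((data - offset[:, None]) / scale[:, None])
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        # record-major layout: for each 1 s record, all channels in sequence
        for r in range(n_rec):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())


def read_recording(path) -> Recording:
    """Load an EDF file as a Recording in microvolts at native rate.

    Raises
    ------
    ValueError
        If any channel contains NaN samples (offending channels listed).
    """
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data(units="uV")
    bad = [name for name, row in zip(raw.ch_names, data) if not np.isfinite(row).all()]
    if bad:
        raise ValueError(f"non-finite samples in channel(s): {', '.join(bad)}")
    return Recording(data=data, fs=float(raw.info["sfreq"]), ch_names=list(raw.ch_names))


# ---------------------------------------------------------------------------
# event tables and metadata TSVs
# ---------------------------------------------------------------------------

def empty_event_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject": pd.Series(dtype=str),
            "channel": pd.Series(dtype=str),
            "start_s": pd.Series(dtype=float),
            "end_s": pd.Series(dtype=float),
            "detector": pd.Series(dtype=str),
            "tags": pd.Series(dtype=str),
        }
    )


def _validate_events(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"event table missing column(s): {', '.join(missing)}")
    bad = table.index[table["end_s"] <= table["start_s"]]
    if len(bad):
        raise ValueError(f"event rows with end_s <= start_s: {list(bad[:10])}")
    return table[EVENT_COLUMNS]


def write_event_table(table: pd.DataFrame, path) -> None:
    """Serialize events as TSV; times carry microsecond precision."""
    out = _validate_events(table.copy())
    out["start_s"] = out["start_s"].map(lambda v: f"{v:.6f}")
    out["end_s"] = out["end_s"].map(lambda v: f"{v:.6f}")
    out["tags"] = out["tags"].fillna("")
    out.to_csv(path, sep="\t", index=False)


def read_event_table(path) -> pd.DataFrame:
    table = pd.read_csv(
        path, sep="\t", dtype={"subject": str, "channel": str, "detector": str, "tags": str}
    )
    if table.empty and list(table.columns) == EVENT_COLUMNS:
        return empty_event_table()
    table["tags"] = table.get("tags", pd.Series(dtype=str)).fillna("")
    return _validate_events(table).reset_index(drop=True)


def read_channel_metadata(path) -> pd.DataFrame:
    """channels.tsv: name, type (grid|depth), soz, resected, bad (0/1)."""
    meta = pd.read_csv(path, sep="\t", dtype={"name": str, "type": str, "subject": str})
    required = {"name", "type", "soz", "resected", "bad"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"channels.tsv missing column(s): {', '.join(sorted(missing))}")
    for col in ("soz", "resected", "bad"):
        meta[col] = meta[col].astype(int).astype(bool)
    return meta


def read_subject_metadata(path) -> pd.DataFrame:
    """subjects.tsv: id, site, sex, age, pathology, resected, engel1."""
    meta = pd.read_csv(path, sep="\t", dtype={"id": str, "site": str, "sex": str})
    required = {"id", "site", "sex", "age", "pathology", "engel1"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"subjects.tsv missing column(s): {', '.join(sorted(missing))}")
    meta["engel1"] = meta["engel1"].astype(int).astype(bool)
    if "resected" in meta.columns:
        meta["resected"] = meta["resected"].astype(int).astype(bool)
    return meta


# ---------------------------------------------------------------------------
# HDF5 image stores
# ---------------------------------------------------------------------------

def write_image_store(path, images: np.ndarray, index: pd.DataFrame) -> None:
    """Store per-event 64x64 images with a (subject, channel, center_s) index.

    The index permits random access for stratified subject sampling.
    """
    images = np.asarray(images, dtype=np.float32)
    if images.ndim != 3:
        raise ValueError("images must be (n, h, w)")
    if len(index) != images.shape[0]:
        raise ValueError("index length must match image count")
    with h5py.File(path, "w") as fh:
        fh.create_dataset("images", data=images)
        fh.create_dataset(
            "subject", data=np.array(index["subject"], dtype=h5py.string_dtype())
        )
        fh.create_dataset(
            "channel", data=np.array(index["channel"], dtype=h5py.string_dtype())
        )
        fh.create_dataset("center_s", data=np.asarray(index["center_s"], dtype=np.float64))


def read_image_store(path) -> tuple[np.ndarray, pd.DataFrame]:
    with h5py.File(path, "r") as fh:
        images = fh["images"][:]
        index = pd.DataFrame(
            {
                "subject": [s.decode() for s in fh["subject"][:]],
                "channel": [s.decode() for s in fh["channel"][:]],
                "center_s": fh["center_s"][:],
            }
        )
    return images, index


# ---------------------------------------------------------------------------
# classifier bundles
# ---------------------------------------------------------------------------

_GMM_ATTRS = ["weights_", "means_", "covariances_", "precisions_cholesky_"]


def _write_gmm(group, gmm) -> None:
    group.attrs["n_components"] = gmm.n_components
    group.attrs["covariance_type"] = gmm.covariance_type
    for attr in _GMM_ATTRS:
        group.create_dataset(attr, data=getattr(gmm, attr))


def _read_gmm(group):
    from sklearn.mixture import GaussianMixture

    gmm = GaussianMixture(
        n_components=int(group.attrs["n_components"]),
        covariance_type=str(group.attrs["covariance_type"]),
    )
    for attr in _GMM_ATTRS:
        setattr(gmm, attr, group[attr][:])
    gmm.converged_ = True
    return gmm


def save_bundle(classifier, path) -> None:
    """Serialize a trained HfoClassifier (VAE + both GMMs + label map)."""
    from .cluster import HfoClassifier  # noqa: F401  (type reference)

    with h5py.File(path, "w") as fh:
        fh.attrs["bundle_version"] = BUNDLE_VERSION
        vae_grp = fh.create_group("vae")
        vae_grp.attrs["config"] = json.dumps(classifier.vae.config.to_dict())
        for name, value in classifier.vae.params.items():
            vae_grp.create_dataset(name, data=value)
        _write_gmm(fh.create_group("gmm_stage1"), classifier.stage1_gmm)
        _write_gmm(fh.create_group("gmm_stage2"), classifier.stage2_gmm)
        fh.attrs["artifact_cluster"] = int(classifier.artifact_cluster)
        if classifier.pathological_cluster is None:
            raise BundleError("refusing to save bundle with unlabeled clusters")
        fh.attrs["pathological_cluster"] = int(classifier.pathological_cluster)
        fh.attrs["err_mean"] = float(classifier.err_mean)
        fh.attrs["err_std"] = float(classifier.err_std)
        fh.attrs["err_weight"] = float(classifier.err_weight)
        fh.attrs["seed"] = int(classifier.seed)


def load_bundle(path):
    """Load a classifier bundle; inverse of :func:`save_bundle`."""
    from .cluster import HfoClassifier
    from .vae import TrainedVae, VaeConfig

    try:
        with h5py.File(path, "r") as fh:
            version = int(fh.attrs.get("bundle_version", -1))
            if version != BUNDLE_VERSION:
                raise BundleError(
                    f"incompatible bundle version {version} (expected {BUNDLE_VERSION})"
                )
            if "pathological_cluster" not in fh.attrs:
                raise BundleError("bundle has unlabeled clusters")
            cfg = VaeConfig.from_dict(json.loads(fh["vae"].attrs["config"]))
            params = {
                name: fh["vae"][name][:]
                for name in fh["vae"]
            }
            vae = TrainedVae(config=cfg, params=params)
            gmm1 = _read_gmm(fh["gmm_stage1"])
            gmm2 = _read_gmm(fh["gmm_stage2"])
            return HfoClassifier(
                vae=vae,
                stage1_gmm=gmm1,
                artifact_cluster=int(fh.attrs["artifact_cluster"]),
                stage2_gmm=gmm2,
                pathological_cluster=int(fh.attrs["pathological_cluster"]),
                err_mean=float(fh.attrs["err_mean"]),
                err_std=float(fh.attrs["err_std"]),
                err_weight=float(fh.attrs["err_weight"]),
                seed=int(fh.attrs["seed"]),
            )
    except (OSError, KeyError) as exc:
        raise BundleError(f"unreadable classifier bundle: {exc}") from exc
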