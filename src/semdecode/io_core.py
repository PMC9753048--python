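"""Core domain types and file I/O for intracranial decoding analyses.

The pipeline operates on three pieces of session data:

* a :class:`Recording` — continuous multichannel ECoG in microvolts,
* an :class:`ElectrodeTable` — gyrus label, hemisphere and language
  dominance per channel,
* an :class:`EventList` — stimulus onsets with word identity and the
  abstract/concrete category factor.

Recordings are stored losslessly in a single HDF5 container; EDF is
supported read-only (its 16-bit quantization makes it unsuitable as an
internal format).  Electrode and event tables are plain TSV.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "REGIONS",
    "CATEGORIES",
    "CATEGORY_CODES",
    "Recording",
    "ElectrodeTable",
    "EventList",
    "AnalysisConfig",
    "read_recording",
    "write_recording",
    "read_electrode_table",
    "write_electrode_table",
    "read_events",
    "write_events",
    "load_table2_fixture",
]

#: Closed vocabulary of anatomical region labels attached to electrodes:
#: superior/middle/inferior frontal gyrus, superior/middle/inferior temporal
#: gyrus, angular gyrus, supramarginal gyrus, primary sensorimotor cortex,
#: and a catch-all for electrodes outside these gyri.
REGIONS = ("SFG", "MFG", "IFG", "STG", "MTG", "ITG", "AG", "SMG", "SM1", "other")

CATEGORIES = ("abstract", "concrete")

#: Internal numeric encoding of the category factor.  Abstract = +1 and
#: concrete = -1 fixes the sign convention of SVM weights and of the
#: deviation index throughout the package (positive = abstract-dominant).
CATEGORY_CODES = {"abstract": 1, "concrete": -1}


class FormatError(ValueError):
    """A file could not be parsed in the declared format."""


class IntegrityError(ValueError):
    """Parsed data violate a structural invariant."""


@dataclass
class Recording:
    """Continuous multichannel signal.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Voltage in microvolts.
    rate : float
        Sampling rate in Hz.
    channel_ids : tuple of str
        Unique channel labels, one per signal row.
    """

    signal: np.ndarray
    rate: float
    channel_ids: tuple

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        self.channel_ids = tuple(str(c) for c in self.channel_ids)
        if self.rate <= 0:
            raise IntegrityError(f"sampling rate must be positive, got {self.rate}")
        if self.signal.ndim != 2:
            raise IntegrityError("signal must be a channel x sample matrix")
        if len(self.channel_ids) != self.signal.shape[0]:
            raise IntegrityError(
                f"{len(self.channel_ids)} channel ids for {self.signal.shape[0]} signal rows"
            )
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise IntegrityError("channel_ids must be unique")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.rate


@dataclass
class ElectrodeTable:
    """Per-channel anatomical metadata.

    Wraps a DataFrame with columns ``channel_id``, ``region``,
    ``hemisphere`` and ``dominant``; regions come from the closed
    vocabulary :data:`REGIONS`.
    """

    table: pd.DataFrame

    def __post_init__(self):
        df = pd.DataFrame(self.table).copy()
        required = ["channel_id", "region", "hemisphere", "dominant"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"electrode table missing columns: {missing}")
        df["channel_id"] = df["channel_id"].astype(str)
        if df["channel_id"].duplicated().any():
            dupes = df.loc[df["channel_id"].duplicated(), "channel_id"].tolist()
            raise IntegrityError(f"duplicate channel ids: {dupes}")
        bad = df.loc[~df["region"].isin(REGIONS)]
        if len(bad):
            row = bad.iloc[0]
            raise IntegrityError(
                f"unknown region {row['region']!r} for channel {row['channel_id']!r}; "
                f"allowed labels: {', '.join(REGIONS)}"
            )
        if not df["hemisphere"].isin(["left", "right"]).all():
            raise IntegrityError("hemisphere must be 'left' or 'right'")
        df["dominant"] = df["dominant"].astype(bool)
        self.table = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def region_of(self) -> dict:
        """Map channel_id -> region label."""
        return dict(zip(self.table["channel_id"], self.table["region"]))

    def channels_in(self, region: str) -> list:
        """Channel ids assigned to ``region``."""
        sel = self.table["region"] == region
        return self.table.loc[sel, "channel_id"].tolist()

    def region_indices(self, channel_ids) -> dict:
        """Map region -> indices into ``channel_ids`` (analysis channel order)."""
        region_of = self.region_of()
        out: dict = {}
        for i, ch in enumerate(channel_ids):
            if ch not in region_of:
                raise IntegrityError(f"channel {ch!r} missing from electrode table")
            out.setdefault(region_of[ch], []).append(i)
        return {r: np.asarray(ix, dtype=int) for r, ix in out.items()}


@dataclass
class EventList:
    """Stimulus events: onset (seconds from recording start), word id,
    and category ('abstract' or 'concrete'), sorted by onset."""

    onset: np.ndarray
    word_id: np.ndarray
    category: np.ndarray

    def __post_init__(self):
        self.onset = np.asarray(self.onset, dtype=np.float64)
        self.word_id = np.asarray(self.word_id, dtype=object)
        self.category = np.asarray([str(c).lower() for c in np.asarray(self.category)], dtype=object)
        if not (len(self.onset) == len(self.word_id) == len(self.category)):
            raise IntegrityError("event columns have unequal lengths")
        if len(self.onset) == 0:
            raise IntegrityError("event list is empty (no trials)")
        bad = set(self.category) - set(CATEGORIES)
        if bad:
            raise IntegrityError(f"unknown categories {sorted(bad)}; allowed: {CATEGORIES}")
        order = np.argsort(self.onset, kind="stable")
        self.onset = self.onset[order]
        self.word_id = self.word_id[order]
        self.category = self.category[order]
        if np.any(np.diff(self.onset) <= 0):
            raise IntegrityError("event onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.onset)

    @property
    def labels(self) -> np.ndarray:
        """Numeric labels: abstract = +1, concrete = -1."""
        return np.asarray([CATEGORY_CODES[c] for c in self.category], dtype=int)

    def subset(self, mask) -> "EventList":
        mask = np.asarray(mask)
        return EventList(self.onset[mask], self.word_id[mask], self.category[mask])


@dataclass
class AnalysisConfig:
    """Parameters of the high-gamma decoding analysis.

    Defaults follow the canonical paradigm: 70-150 Hz band, epochs from
    500 ms before to 2000 ms after stimulus onset, 250-ms power bins,
    six analysis bins covering 0-1500 ms, a 500-ms pre-stimulus baseline,
    rank-sum feature selection at alpha = 0.05, and a binomial chance
    threshold at alpha = 0.05.
    """

    band_low: float = 70.0
    band_high: float = 150.0
    epoch_start_ms: float = -500.0
    epoch_end_ms: float = 2000.0
    bin_width_ms: float = 250.0
    analysis_window_ms: tuple = (0.0, 1500.0)
    baseline_window_ms: tuple = (-500.0, 0.0)
    selection_alpha: float = 0.05
    chance_alpha: float = 0.05
    smoothing_width_ms: float = 25.0
    svm_C: float = 1.0
    reject_k: float = 5.0
    random_seed: int = 0

    def __post_init__(self):
        if not 0 < self.band_low < self.band_high:
            raise IntegrityError("need 0 < band_low < band_high")
        for name, (lo, hi) in (
            ("epoch", (self.epoch_start_ms, self.epoch_end_ms)),
            ("analysis_window", tuple(self.analysis_window_ms)),
            ("baseline_window", tuple(self.baseline_window_ms)),
        ):
            if hi <= lo:
                raise IntegrityError(f"{name} window is empty: [{lo}, {hi}]")
            for edge in (lo, hi):
                if abs(edge / self.bin_width_ms - round(edge / self.bin_width_ms)) > 1e-9:
                    raise IntegrityError(
                        f"{name} edge {edge} ms is not a multiple of bin width {self.bin_width_ms} ms"
                    )
        if not (self.epoch_start_ms <= self.baseline_window_ms[0]
                and self.baseline_window_ms[1] <= self.epoch_end_ms):
            raise IntegrityError("baseline window must lie inside the epoch")
        if not (self.epoch_start_ms <= self.analysis_window_ms[0]
                and self.analysis_window_ms[1] <= self.epoch_end_ms):
            raise IntegrityError("analysis window must lie inside the epoch")
        if not 0 < self.selection_alpha < 1:
            raise IntegrityError("selection_alpha must be in (0, 1)")
        if not 0 < self.chance_alpha < 1:
            raise IntegrityError("chance_alpha must be in (0, 1)")

    # Derived bin bookkeeping -------------------------------------------------
    @property
    def n_bins(self) -> int:
        """Total bins spanning the epoch (10 for the canonical windows)."""
        return int(round((self.epoch_end_ms - self.epoch_start_ms) / self.bin_width_ms))

    @property
    def bin_edges_ms(self) -> np.ndarray:
        return self.epoch_start_ms + self.bin_width_ms * np.arange(self.n_bins + 1)

    def _bin_range(self, window_ms) -> np.ndarray:
        lo = int(round((window_ms[0] - self.epoch_start_ms) / self.bin_width_ms))
        hi = int(round((window_ms[1] - self.epoch_start_ms) / self.bin_width_ms))
        return np.arange(lo, hi)

    @property
    def analysis_bins(self) -> np.ndarray:
        """Indices (into the epoch bins) of the analysis bins; 6 canonical."""
        return self._bin_range(self.analysis_window_ms)

    @property
    def baseline_bins(self) -> np.ndarray:
        return self._bin_range(self.baseline_window_ms)

    @property
    def analysis_bin_edges_ms(self) -> np.ndarray:
        """Edges (ms) of the analysis bins, length n_analysis_bins + 1."""
        b = self.analysis_bins
        return self.bin_edges_ms[b[0]: b[-1] + 2]

    def replace(self, **kw) -> "AnalysisConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# Recording container I/O
# ---------------------------------------------------------------------------

def write_recording(path, rec: Recording, **metadata) -> None:
    """Write a Recording to the single-file HDF5 container.

    Extra keyword arguments are stored as provenance attributes.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=rec.signal)
        f.attrs["rate"] = float(rec.rate)
        f.create_dataset(
            "channel_ids", data=np.asarray(rec.channel_ids, dtype=h5py.string_dtype())
        )
        for k, v in metadata.items():
            f.attrs[k] = v


def read_recording(path, format: str = "internal") -> Recording:
    """Read a Recording from disk.

    Parameters
    ----------
    path : str or Path
    format : {'internal', 'edf'}
        'internal' is the package HDF5 container; 'edf' reads European
        Data Format via MNE (signal converted to microvolts).
    """
    if format == "internal":
        try:
            with h5py.File(path, "r") as f:
                signal = f["signal"][()]
                rate = float(f.attrs["rate"])
                channel_ids = [c.decode() if isinstance(c, bytes) else str(c)
                               for c in f["channel_ids"][()]]
        except (OSError, KeyError) as e:
            raise FormatError(f"could not read container {path}: {e}") from e
        return Recording(signal=signal, rate=rate, channel_ids=tuple(channel_ids))
    if format == "edf":
        import mne

        try:
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        except Exception as e:  # mne raises several concrete types
            raise FormatError(f"could not read EDF {path}: {e}") from e
        # MNE returns volts; the package convention is microvolts.
        return Recording(
            signal=raw.get_data() * 1e6,
            rate=float(raw.info["sfreq"]),
            channel_ids=tuple(raw.ch_names),
        )
    raise FormatError(f"unknown recording format {format!r}")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_electrode_table(path) -> ElectrodeTable:
    """Read a TSV with columns channel_id, region, hemisphere, dominant."""
    df = pd.read_csv(path, sep="\t", dtype={"channel_id": str})
    if "dominant" in df.columns and df["dominant"].dtype == object:
        df["dominant"] = df["dominant"].astype(str).str.lower().isin(["true", "1", "yes"])
    return ElectrodeTable(df)


def write_electrode_table(path, electrodes: ElectrodeTable) -> None:
    electrodes.table.to_csv(path, sep="\t", index=False)


def read_events(path) -> EventList:
    """Read a TSV with columns onset_s, word_id, category (rows may be in
    any order on disk; the returned list is sorted by onset)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("onset_s", "word_id", "category") if c not in df.columns]
    if missing:
        raise FormatError(f"event table missing columns: {missing}")
    return EventList(df["onset_s"].to_numpy(), df["word_id"].to_numpy(), df["category"].to_numpy())


def write_events(path, events: EventList) -> None:
    pd.DataFrame(
        {"onset_s": events.onset, "word_id": events.word_id, "category": events.category}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Packaged worked-example fixture
# ---------------------------------------------------------------------------

def load_table2_fixture() -> pd.DataFrame:
    """Per-participant decoding results used as the worked-example surface.

    Nine participants (P1-P9, language-dominant hemisphere) with
    full-feature and targeted decoding accuracy (%), their difference
    ("reduction"), and retained-feature counts in the IFG, SM1 and all
    other regions.
    """
    ref = importlib.resources.files("semdecode.data").joinpath("table2.tsv")
    with importlib.resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t")
    return df
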