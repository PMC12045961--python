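"""Optional adapter for WFDB-format intrapartum CTG records.

Maps records in the layout of the open CTU-UHB intrapartum database
(signals ``FHR`` and ``UC`` at 4 Hz, clinical metadata in the header
comments) onto :class:`~ctgartifact.signal_quality.CTGRecord`.  Requires
the ``wfdb`` package, which is not a dependency of this package; the
import is deferred so nothing else needs it.  No maternal channel exists
in these records, so coincidence is unavailable downstream.
"""

from __future__ import annotations

from .signal_quality import CTGRecord


def load_wfdb_record(record_path: str, fhr_channel: str = "FHR") -> CTGRecord:
    """Read one WFDB record into a CTGRecord (delivery at end of trace)."""
    try:
        import wfdb  # type: ignore[import-not-found]
    except ImportError as exc:  # pragma: no cover - wfdb optional
        raise ImportError(
            "the WFDB adapter requires the optional 'wfdb' package"
        ) from exc
    rec = wfdb.rdrecord(record_path)
    names = list(rec.sig_name)
    if fhr_channel not in names:
        raise ValueError(f"channel {fhr_channel!r} not in record ({names})")
    fhr = rec.p_signal[:, names.index(fhr_channel)]
    fhr = fhr.copy()
    fhr[~(fhr > 0)] = 0.0  # NaN or negative -> dropout
    n = fhr.shape[0]
    return CTGRecord(
        episode_id=str(record_path).rsplit("/", 1)[-1],
        fhr=fhr,
        sampling_rate=float(rec.fs),
        mhr=None,
        acq_active=None,
        delivery_offset_s=n / float(rec.fs),
    )
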