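import numpy as np
import pytest

from ctgartifact.signal_quality import AnalysisWindow, CTGRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_window(
    fhr, mhr=None, acq=None, fs=4.0, episode_id="ep-test"
) -> AnalysisWindow:
    fhr = np.asarray(fhr, dtype=float)
    return AnalysisWindow(
        episode_id=episode_id,
        fhr=fhr,
        sampling_rate=fs,
        mhr=None if mhr is None else np.asarray(mhr, dtype=float),
        acq_active=None if acq is None else np.asarray(acq, dtype=bool),
    )


def make_record(n=14400, fs=4.0, fhr_value=140.0, **kwargs) -> CTGRecord:
    return CTGRecord(
        episode_id=kwargs.pop("episode_id", "ep-test"),
        fhr=np.full(n, fhr_value),
        sampling_rate=fs,
        delivery_offset_s=kwargs.pop("delivery_offset_s", n / fs),
        **kwargs,
    )


@pytest.fixture
def trace_file_factory(tmp_path):
    """Write a well-formed trace CSV and return its path."""

    def write(
        name="ep000001",
        n=240,
        fs=4.0,
        fhr=None,
        mhr=None,
        acq=None,
        delivery_offset_s=None,
        header_extra="",
    ):
        path = tmp_path / f"{name}.csv"
        t = np.arange(n) / fs
        fhr = np.full(n, 140.0) if fhr is None else np.asarray(fhr, float)
        cols = ["t_s", "fhr_bpm"]
        data = [t, fhr]
        if mhr is not None:
            cols.append("mhr_bpm")
            data.append(np.asarray(mhr, float))
        if acq is not None:
            cols.append("acq_active")
            data.append(np.asarray(acq, int))
        offset = n / fs if delivery_offset_s is None else delivery_offset_s
        lines = [f"# delivery_offset_s={offset}", f"# sampling_rate={fs}"]
        if header_extra:
            lines.append(header_extra)
        lines.append(",".join(cols))
        for i in range(n):
            lines.append(",".join(str(d[i]) for d in data))
        path.write_text("\n".join(lines) + "\n")
        return path

    return write
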