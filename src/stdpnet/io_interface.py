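"""Configuration presets, config-file round-tripping and run outputs.

Presets named ``fig2`` ... ``fig9c`` carry the published simulation
parameters verbatim (network size, maximum weight, synaptic and STDP time
constants, amplitudes, learning rate and spontaneous rate), together with the
per-protocol options (initial-weight fraction, stimulation parameters,
low-rate neuron index and so on).  Configs serialise to YAML and round-trip
losslessly; run outputs are plain-text spike files, an ``.npz`` snapshot
container and a YAML manifest with seeds and a config hash.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .model_core import InvalidParameterError, NetworkConfig, STDPWindow


@dataclass
class Preset:
    name: str
    config: NetworkConfig
    window: STDPWindow
    options: dict = field(default_factory=dict)

    def with_seed(self, seed: int) -> "Preset":
        cfg = NetworkConfig(
            N=self.config.N,
            w_max=self.config.w_max,
            tau_s=self.config.tau_s,
            lambda0=self.config.lambda0.copy(),
            mask=None if self.config.mask is None else self.config.mask.copy(),
            seed=seed,
        )
        return Preset(self.name, cfg, self.window, dict(self.options))


# STDP window shapes shared by several presets
_WIN_A = dict(A_p=0.08, A_d=-0.0533, tau_p=0.025, tau_d=0.05)     # fig2/3, fig6b, fig8*, fig9*
_WIN_B = dict(A_p=0.08, A_d=-0.066, tau_p=0.035, tau_d=0.05)      # fig4
_WIN_C = dict(A_p=0.08, A_d=-0.044, tau_p=0.022, tau_d=0.055)     # fig5, fig6a
_WIN_D = dict(A_p=0.08, A_d=-0.042, tau_p=0.026, tau_d=0.065)     # fig7

_PRESET_TABLE: dict[str, dict] = {
    "fig2": dict(N=120, w_max=0.04, tau_s=0.01, mu=0.07, lambda0=0.15, win=_WIN_A,
                 options=dict(init_fraction=0.25)),
    "fig3a": dict(N=10, w_max=0.04, tau_s=0.01, mu=1.0, lambda0=0.15, win=_WIN_A,
                  options=dict(purpose="homogeneous-assembly drift curves")),
    "fig3b": dict(N=150, w_max=0.04, tau_s=0.01, mu=0.04, lambda0=0.15, win=_WIN_A,
                  options=dict(init_fraction=0.20, n_seeds=10)),
    "fig4": dict(N=80, w_max=0.026, tau_s=0.01, mu=0.07, lambda0=0.15, win=_WIN_B,
                 options=dict(init_fraction=0.25, assembly=list(range(0, 20)),
                              stim_group=list(range(20, 40)), stim_rate=4.18,
                              w_in_factor=10.0, T_stim=180.0)),
    "fig5": dict(N=120, w_max=0.017, tau_s=0.01, mu=0.02, lambda0=0.15, win=_WIN_C,
                 options=dict(assembly_size=20)),
    "fig6a": dict(N=60, w_max=0.0158, tau_s=0.01, mu=0.021, lambda0=0.15, win=_WIN_C,
                  options=dict(assembly_size=20, overlap_neuron=9, overlap_lambda0=0.08,
                               mode="completion")),
    "fig6b": dict(N=60, w_max=0.024, tau_s=0.01, mu=0.045, lambda0=0.15, win=_WIN_A,
                  options=dict(assembly_size=20, overlap_neuron=9, overlap_lambda0=0.01,
                               mode="emergence")),
    "fig7": dict(N=190, w_max=0.018, tau_s=0.01, mu=0.017, lambda0=0.15, win=_WIN_D,
                 options=dict(n_A=19)),
    "fig8a": dict(N=72, w_max=0.056, tau_s=0.01, mu=0.1, lambda0=0.2, win=_WIN_A,
                  options=dict(init_fraction=0.15, mu_low=0.1, mu_high=0.145)),
    "fig8b": dict(N=120, w_max=0.024, tau_s=0.01, mu=0.05, lambda0=0.15, win=_WIN_A,
                  options=dict(epoch_length=3e5, switch_prob=0.03, low_rate=0.03)),
    "fig9a": dict(N=10, w_max=0.058, tau_s=0.01, mu=1.0, lambda0=0.15, win=_WIN_A,
                  options=dict(purpose="sparse-assembly drift curves")),
    "fig9b": dict(N=120, w_max=0.058, tau_s=0.01, mu=0.07, lambda0=0.15, win=_WIN_A,
                  options=dict(init_fraction=0.25, p_after=0.7)),
    "fig9c": dict(N=150, w_max=0.067, tau_s=0.01, mu=0.05, lambda0=0.2, win=_WIN_A,
                  options=dict(purpose="(p, mu) sweep of spontaneous sizes")),
}


def preset_names() -> list[str]:
    return sorted(_PRESET_TABLE)


def get_preset(name: str, seed: int = 0) -> Preset:
    """Build a named parameter preset (Table-1 values)."""
    if name not in _PRESET_TABLE:
        raise KeyError(f"unknown preset {name!r}; available: {preset_names()}")
    row = _PRESET_TABLE[name]
    window = STDPWindow(mu=row["mu"], **row["win"])
    config = NetworkConfig(
        N=row["N"], w_max=row["w_max"], tau_s=row["tau_s"], lambda0=row["lambda0"],
        seed=seed,
    )
    return Preset(name, config, window, dict(row["options"]))


# ---------------------------------------------------------------------------
# config serialisation

_CONFIG_KEYS = {"N", "w_max", "tau_s", "lambda0", "seed"}
_WINDOW_KEYS = {"A_p", "A_d", "tau_p", "tau_d", "mu"}


def dump_config(config: NetworkConfig, window: STDPWindow, options: dict | None = None) -> str:
    lam = config.lambda0
    lam_out = float(lam[0]) if np.allclose(lam, lam[0]) else [float(v) for v in lam]
    doc = {
        "network": {
            "N": int(config.N), "w_max": float(config.w_max),
            "tau_s": float(config.tau_s), "lambda0": lam_out, "seed": int(config.seed),
        },
        "window": {
            "A_p": float(window.A_p), "A_d": float(window.A_d),
            "tau_p": float(window.tau_p), "tau_d": float(window.tau_d),
            "mu": float(window.mu),
        },
        "options": options or {},
    }
    return yaml.safe_dump(doc, sort_keys=True)


def save_config(path: str | Path, config: NetworkConfig, window: STDPWindow,
                options: dict | None = None) -> None:
    Path(path).write_text(dump_config(config, window, options))


def load_config(path: str | Path) -> tuple[NetworkConfig, STDPWindow, dict]:
    """Parse and validate a YAML config; unknown keys are rejected."""
    try:
        doc = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as e:
        raise InvalidParameterError("config", f"YAML parse error: {e}") from e
    if not isinstance(doc, dict) or "network" not in doc or "window" not in doc:
        raise InvalidParameterError("config", "expected top-level 'network' and 'window'")
    net = doc["network"]
    win = doc["window"]
    for key in net:
        if key not in _CONFIG_KEYS:
            raise InvalidParameterError(key, "unknown network key")
    for key in win:
        if key not in _WINDOW_KEYS:
            raise InvalidParameterError(key, "unknown window key")
    for req in ("N", "w_max", "tau_s", "lambda0"):
        if req not in net:
            raise InvalidParameterError(req, "missing required network field")
    for req in ("A_p", "A_d", "tau_p", "tau_d"):
        if req not in win:
            raise InvalidParameterError(req, "missing required window field")
    config = NetworkConfig(
        N=int(net["N"]), w_max=float(net["w_max"]), tau_s=float(net["tau_s"]),
        lambda0=net["lambda0"], seed=int(net.get("seed", 0)),
    )
    window = STDPWindow(
        A_p=float(win["A_p"]), A_d=float(win["A_d"]),
        tau_p=float(win["tau_p"]), tau_d=float(win["tau_d"]),
        mu=float(win.get("mu", 1.0)),
    )
    return config, window, doc.get("options", {}) or {}


def config_hash(config: NetworkConfig, window: STDPWindow, options: dict | None = None) -> str:
    return hashlib.sha256(dump_config(config, window, options).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# weight-matrix text format


def save_weights_text(path: str | Path, W: np.ndarray, w_max: float) -> None:
    W = np.asarray(W, dtype=float)
    header = f"N={W.shape[0]} w_max={w_max!r}"
    np.savetxt(path, W, header=header, fmt="%.9g", delimiter="\t")


def load_weights_text(path: str | Path) -> tuple[np.ndarray, float]:
    with open(path) as fh:
        header = fh.readline().lstrip("# ").strip()
    meta = dict(kv.split("=") for kv in header.split())
    W = np.loadtxt(path, delimiter="\t")
    return np.atleast_2d(W), float(meta["w_max"])


def save_cover_text(path: str | Path, cover) -> None:
    lines = [" ".join(str(i) for i in sorted(a)) for a in cover]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def load_cover_text(path: str | Path):
    from .model_core import AssemblyCover

    assemblies = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line:
            assemblies.append(frozenset(int(v) for v in line.split()))
    return AssemblyCover(assemblies)


# ---------------------------------------------------------------------------
# run outputs


def write_outputs(
    run_dir: str | Path,
    record=None,
    snapshots=None,
    report: dict | None = None,
    config: NetworkConfig | None = None,
    window: STDPWindow | None = None,
    options: dict | None = None,
    seeds: list[int] | None = None,
    gzip_spikes: bool = False,
) -> dict:
    """Write spikes, snapshots, report and manifest under ``run_dir``.

    Spikes go to a flat three-column text file (time_s to 9 significant
    digits, neuron_id, source_tag), optionally gzip-compressed, snapshots
    to an ``.npz`` with their time index, the report to YAML.  Returns the
    manifest (also written).
    """
    import gzip

    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"files": {}}
    if record is not None:
        spike_path = run_dir / ("spikes.tsv.gz" if gzip_spikes else "spikes.tsv")
        opener = (lambda p: gzip.open(p, "wt")) if gzip_spikes else (lambda p: open(p, "w"))
        with opener(spike_path) as fh:
            fh.write("time_s\tneuron_id\tsource_tag\n")
            for t, i in zip(record.times, record.ids):
                tag = "network" if i < record.N else f"source-{int(i) - record.N}"
                nid = int(i) if i < record.N else int(i) - record.N
                fh.write(f"{t:.9g}\t{nid}\t{tag}\n")
        manifest["files"]["spikes"] = spike_path.name
        manifest["n_events"] = int(len(record))
    if snapshots:
        times = np.asarray([t for t, _ in snapshots])
        stack = np.stack([W for _, W in snapshots])
        np.savez_compressed(run_dir / "snapshots.npz", times=times, weights=stack)
        manifest["files"]["snapshots"] = "snapshots.npz"
    if report is not None:
        (run_dir / "report.yaml").write_text(yaml.safe_dump(_yamlable(report), sort_keys=False))
        manifest["files"]["report"] = "report.yaml"
    if config is not None and window is not None:
        save_config(run_dir / "config.yaml", config, window, options)
        manifest["files"]["config"] = "config.yaml"
        manifest["config_hash"] = config_hash(config, window, options)
    if seeds is not None:
        manifest["seeds"] = [int(s) for s in seeds]
    from . import __version__

    manifest["version"] = __version__
    (run_dir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest


def _yamlable(obj):
    """Recursively convert numpy scalars/arrays for YAML output."""
    if isinstance(obj, dict):
        return {str(k): _yamlable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yamlable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, frozenset):
        return sorted(obj)
    return obj
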