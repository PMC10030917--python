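"""Virtual-experiment files: parse and execute a scripted workflow.

An experiment file is a plain-text list of directives, one per line
(``--`` and ``#`` start comments; directives are case-sensitive)::

    Sampling 200 (Trail=0)
    Modules (EMT, Apoptotic_SW)
    Pulse1 41 Stiff_ECM 100
    Async_Pulse1 41 Stiff_ECM 100
    NonSaturating_Draw 218 (GF=1, GF_High=0.95, Stiff_ECM=0.75) (J_Ecadherin KD 0.95)
    NonSaturating_Stats_Scan_1Env_fnKDOE 34 GF_High (Stiff_ECM=0.9, GF=1) (p53 KD)
    ModelErrors_Pulse1 31 GF_High 100 15

Numeric attractor IDs refer to the run-local IDs of the cached sampling
report (written to ``id_map.csv``); sampling results are cached per model
content hash, so IDs remain stable as long as the model is unchanged.
Every artifact embeds the model hash and the RNG seed.
"""

from __future__ import annotations

import json
import logging
import os
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .attractors import SamplingReport, sample_attractors
from .model import BooleanNetworkModel, parse_model
from .perturbation import InputSchedule, KdOeSpec, run_pulse_experiment, scan_1env
from .phenotypes import load_default_signatures, run_phenotype_statistics
from .reduction import MutantSpec, generate_mutant_ensemble, isolate_module

__all__ = ["ExperimentError", "parse_experiment_file", "run_experiment_file"]

log = logging.getLogger(__name__)

_PAREN = re.compile(r"\(([^()]*)\)")


class ExperimentError(ValueError):
    """A directive line could not be parsed or executed."""


def _parse_assignments(body: str) -> dict[str, float]:
    out: dict[str, float] = {}
    body = body.strip()
    if not body:
        return out
    for part in body.split(","):
        name, _, val = part.partition("=")
        if not _:
            raise ExperimentError(f"expected name=value, got {part.strip()!r}")
        out[name.strip()] = float(val.strip())
    return out


def _parse_kdoe(body: str) -> KdOeSpec:
    toks = body.split()
    if len(toks) not in (2, 3) or toks[1] not in ("KD", "OE"):
        raise ExperimentError(f"expected '<node> KD|OE [prob]', got {body!r}")
    prob = float(toks[2]) if len(toks) == 3 else 1.0
    return KdOeSpec(node=toks[0], mode=toks[1], probability=prob)


@dataclass
class Directive:
    lineno: int
    kind: str
    args: dict = field(default_factory=dict)


_PULSE = re.compile(r"^(?P<async>Async_)?Pulse\d*$")
_ERRPULSE = re.compile(r"^ModelErrors_Pulse\d*$")
_SCAN = re.compile(r"^(?P<async>AsyncBias_)?NonSaturating_Stats_Scan_1Env_fnKDOE$")


def parse_experiment_file(text: str) -> list[Directive]:
    directives: list[Directive] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("--", 1)[0].split("#", 1)[0].strip()
        if not line:
            continue
        parens = _PAREN.findall(line)
        head = _PAREN.sub("", line).split()
        word = head[0]
        try:
            if word == "Sampling":
                d = Directive(lineno, "sampling", {
                    "n_rnd": int(head[1]),
                    "clamps": {k: int(v) for k, v in
                               _parse_assignments(parens[0]).items()} if parens else {}})
            elif word == "Modules":
                if not parens:
                    raise ExperimentError("Modules requires a (A, B, ...) list")
                names = [s.strip() for s in parens[0].split(",") if s.strip()]
                d = Directive(lineno, "modules", {"modules": names})
            elif _PULSE.match(word):
                d = Directive(lineno, "pulse", {
                    "label": word, "attractor": int(head[1]), "input": head[2],
                    "duration": int(head[3]),
                    "engine": "biased-async" if word.startswith("Async_") else "sync"})
            elif _ERRPULSE.match(word):
                d = Directive(lineno, "model_errors_pulse", {
                    "label": word, "attractor": int(head[1]), "input": head[2],
                    "duration": int(head[3]), "n_errors": int(head[4])})
            elif word == "NonSaturating_Draw":
                d = Directive(lineno, "draw", {
                    "attractor": int(head[1]),
                    "inputs": _parse_assignments(parens[0]),
                    "kdoe": _parse_kdoe(parens[1]) if len(parens) > 1 else None})
            elif _SCAN.match(word):
                d = Directive(lineno, "stats_scan", {
                    "label": word, "attractor": int(head[1]),
                    "scanned_input": head[2],
                    "base": _parse_assignments(parens[0]),
                    "kdoe": _parse_kdoe(parens[1]) if len(parens) > 1 else None,
                    "engine": ("biased-async" if word.startswith("AsyncBias_")
                               else "sync")})
            else:
                raise ExperimentError(f"unknown directive {word!r}")
        except ExperimentError as exc:
            raise ExperimentError(f"line {lineno}: {exc}") from None
        except (IndexError, ValueError) as exc:
            raise ExperimentError(f"line {lineno}: malformed {word!r} directive "
                                  f"({exc})") from None
        directives.append(d)
    return directives


# ---------------------------------------------------------------------------
# execution

def _cache_path(out_dir: str, model: BooleanNetworkModel) -> str:
    return os.path.join(out_dir, f"sampling_{model.content_hash()[:16]}.json")


def _save_report(report: SamplingReport, path: str) -> None:
    payload = {
        "params": report.params,
        "attractors": [
            {"canonical_id": a.canonical_id, "local_id": report.local_ids[cid],
             "period": a.period, "context": list(a.context),
             "states": [list(s) for s in a.states]}
            for cid, a in report.attractors.items()],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def _load_report(path: str) -> SamplingReport:
    from .attractors import Attractor

    with open(path) as fh:
        payload = json.load(fh)
    report = SamplingReport(params=payload["params"])
    for entry in sorted(payload["attractors"], key=lambda e: e["local_id"]):
        att = Attractor(states=tuple(tuple(s) for s in entry["states"]),
                        context=tuple((n, int(b)) for n, b in entry["context"]),
                        canonical_id=entry["canonical_id"],
                        period=entry["period"])
        report.add(att)
    return report


def run_experiment_file(model_path: str, experiment_file: str, out_dir: str,
                        seed: int = 0, ensemble_size: int = 1000) -> dict:
    """Execute every directive in order; write CSV artifacts and a run log.

    Returns a manifest mapping directive labels to artifact paths.  The
    sampling report is cached in ``out_dir`` keyed by the model's content
    hash; a changed model invalidates the cache automatically.
    """
    os.makedirs(out_dir, exist_ok=True)
    with open(model_path) as fh:
        model = parse_model(fh.read(), name=os.path.splitext(
            os.path.basename(model_path))[0])
    with open(experiment_file) as fh:
        directives = parse_experiment_file(fh.read())
    rng = np.random.default_rng(seed)
    manifest: dict[str, str] = {}
    provenance = {"model_hash": model.content_hash(), "seed": seed,
                  "mechbool_version": __version__}
    report: SamplingReport | None = None

    def ensure_sampling(n_rnd=200, clamps=None):
        nonlocal report
        cache = _cache_path(out_dir, model)
        if report is None and os.path.exists(cache):
            report = _load_report(cache)
            log.info("sampling cache hit: %s", cache)
        if report is None:
            report = sample_attractors(model, clamps=clamps, n_rnd=n_rnd,
                                       rng=rng)
            _save_report(report, cache)
            table = report.table(model)
            table.loc["model_hash"] = provenance["model_hash"]
            table.loc["seed"] = seed
            path = os.path.join(out_dir, "attractors.csv")
            table.to_csv(path)
            manifest["Sampling"] = path
            idmap = pd.DataFrame(
                [{"local_id": lid, "canonical_id": cid}
                 for cid, lid in report.local_ids.items()])
            idmap.to_csv(os.path.join(out_dir, "id_map.csv"), index=False)
        return report

    def initial_from(local_id: int):
        rep = ensure_sampling()
        try:
            return rep.by_local_id(local_id)
        except KeyError:
            raise ExperimentError(
                f"attractor ID {local_id} not found in the sampling report "
                f"({len(rep.local_ids)} attractors known)") from None

    def write(df: pd.DataFrame, name: str) -> str:
        path = os.path.join(out_dir, name)
        with open(path, "w") as fh:
            fh.write(f"# model_hash={provenance['model_hash']} seed={seed}\n")
            df.to_csv(fh)
        return path

    for d in directives:
        if d.kind == "sampling":
            ensure_sampling(n_rnd=d.args["n_rnd"], clamps=d.args["clamps"])
        elif d.kind == "modules":
            sub = isolate_module(model, d.args["modules"])
            from .model import serialize_model
            path = os.path.join(out_dir, f"module_{'_'.join(d.args['modules'])}.booleannet")
            with open(path, "w") as fh:
                fh.write(serialize_model(sub))
            subrep = sample_attractors(sub, rng=rng)
            manifest[f"Modules:{d.lineno}"] = write(
                subrep.table(sub), f"module_attractors_{d.lineno}.csv")
        elif d.kind == "pulse":
            att = initial_from(d.args["attractor"])
            res = run_pulse_experiment(model, att, d.args["input"],
                                       d.args["duration"], engine=d.args["engine"],
                                       rng=rng)
            manifest[f"{d.args['label']}:{d.lineno}"] = write(
                res.heatmap, f"pulse_{d.lineno}.csv")
        elif d.kind == "model_errors_pulse":
            att = initial_from(d.args["attractor"])
            frames = []
            for kind in ("node_lock", "link_removal", "gate_flip"):
                spec = MutantSpec(kind=kind,
                                  errors_per_network=d.args["n_errors"],
                                  ensemble_size=ensemble_size)
                on_frac = np.zeros(401)
                count = 0
                for mut in generate_mutant_ensemble(model, spec, rng=rng):
                    res = run_pulse_experiment(mut, att, d.args["input"],
                                               d.args["duration"], rng=rng)
                    on_frac += res.trajectory.mean(axis=1)
                    count += 1
                frames.append(pd.Series(on_frac / max(count, 1), name=kind))
            manifest[f"{d.args['label']}:{d.lineno}"] = write(
                pd.concat(frames, axis=1), f"model_errors_{d.lineno}.csv")
        elif d.kind == "draw":
            att = initial_from(d.args["attractor"])
            schedule = InputSchedule(d.args["inputs"])
            schedule.validate(model)
            from .dynamics import run_trajectory
            kdoe = (d.args["kdoe"],) if d.args["kdoe"] else ()
            for k in kdoe:
                k.validate(model)
            traj = run_trajectory(model, att.state_array(0), "sync", schedule,
                                  400, rng=rng, kdoe=kdoe)
            heat = pd.DataFrame(traj.T, index=pd.Index(model.node_names,
                                                       name="node"))
            manifest[f"NonSaturating_Draw:{d.lineno}"] = write(
                heat, f"draw_{d.lineno}.csv")
        elif d.kind == "stats_scan":
            att = initial_from(d.args["attractor"])
            df = scan_1env(model, att, d.args["scanned_input"], d.args["base"],
                           kdoe=d.args["kdoe"], engine=d.args["engine"],
                           signatures=load_default_signatures(model, strict=False),
                           rng=rng)
            manifest[f"{d.args['label']}:{d.lineno}"] = write(
                df.set_index("level"), f"stats_scan_{d.lineno}.csv")

    if report is None and not directives:
        ensure_sampling()

    logpath = os.path.join(out_dir, "run_log.json")
    with open(logpath, "w") as fh:
        json.dump({**provenance, "directives": len(directives),
                   "artifacts": manifest}, fh, indent=2)
    manifest["run_log"] = logpath
    return manifest
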