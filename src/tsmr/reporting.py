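"""Report-bundle assembly: machine-readable tables and a summary manifest.

The bundle mirrors a standard MR results package: a forest table (per
method: OR, 95% CI, p), the sensitivity report as JSON, the leave-one-out
table, and funnel/scatter source tables from which any plotting layer can
reproduce the usual diagnostic figures.  Rendering of minimal matplotlib
plots is optional; tables are the primary artifact.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from .models import MRResults
from .sensitivity import SensitivityReport, funnel_source, scatter_source


def build_report(
    results: MRResults,
    sensitivity: SensitivityReport | None,
    outdir,
    render_plots: bool = False,
) -> dict:
    """Write the report bundle for one fitted pair; returns the manifest.

    Files: forest.tsv, leave_one_out.tsv, funnel.tsv, scatter.tsv,
    sensitivity.json (or marked absent), summary.json.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    hd = results.model.data

    forest = results.to_frame()
    forest.to_csv(out / "forest.tsv", sep="\t", index=False)
    results.leave_one_out().to_csv(out / "leave_one_out.tsv", sep="\t", index=False)
    funnel_source(hd).to_csv(out / "funnel.tsv", sep="\t", index=False)
    scatter_source(hd).to_csv(out / "scatter.tsv", sep="\t", index=False)

    if sensitivity is not None:
        (out / "sensitivity.json").write_text(
            json.dumps(sensitivity.to_dict(), indent=2, default=float)
        )

    summary = {
        "exposure_id": results.model.exposure_id,
        "outcome_id": results.model.outcome_id,
        "n_snp": results.model.n_snp,
        "estimates": {m: e.to_row() for m, e in results.estimates.items()},
        "sensitivity": "sensitivity.json" if sensitivity is not None else "absent",
        "tables": ["forest.tsv", "leave_one_out.tsv", "funnel.tsv", "scatter.tsv"],
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))

    if render_plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for name, fn in (
            ("scatter", results.plot_scatter),
            ("funnel", results.plot_funnel),
            ("forest", results.plot_forest),
            ("leave_one_out", results.plot_leave_one_out),
        ):
            ax = fn()
            ax.figure.savefig(out / f"{name}.png", dpi=100)
            plt.close(ax.figure)
    return summary


def manifest_hash(outdir) -> str:
    """SHA-256 over the sorted numeric output files of a run directory —
    two runs with identical config and seed must agree."""
    out = Path(outdir)
    digest = hashlib.sha256()
    for path in sorted(out.rglob("*")):
        if path.suffix in (".tsv", ".json") and path.is_file():
            digest.update(path.name.encode())
            digest.update(path.read_bytes())
    return digest.hexdigest()
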