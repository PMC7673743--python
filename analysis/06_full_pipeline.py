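"""One-shot pipeline run: all stages, one seed, one validated JSON report."""
import argparse
import json
from pathlib import Path

from damidreg.pipeline import PipelineConfig, run_pipeline, write_report


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--results", default="results")
    ap.add_argument("--artifacts", default=None,
                    help="optional directory for full stage artifacts")
    args = ap.parse_args()

    cfg = PipelineConfig(seed=args.seed)
    report = run_pipeline(cfg, outdir=args.artifacts)
    res = Path(args.results)
    res.mkdir(parents=True, exist_ok=True)
    write_report(report, res / "06_run_report.json")

    d = report.model_dump()
    print(json.dumps(
        {
            "peaks": d["peaks"],
            "recovery": d["recovery"],
            "enrichment": {k: round(v["fold"], 2) for k, v in d["enrichment"].items()},
            "blue_state_ratio": round(d["chromatin_states"]["ratios"]["blue"], 2),
            "skewness_SD_vs_CD": round(d["expression"]["SD_vs_CD"]["skewness"], 3),
        },
        indent=2,
    ))
    print(f"full report: {res}/06_run_report.json")


if __name__ == "__main__":
    main()
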