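"""Cross-language rank statistics and report emission.

The Kruskal–Wallis H statistic is computed from first principles (pooled
mid-ranks, tie correction, chi-square upper tail via the regularised
incomplete gamma function); the test suite cross-checks it against an
independent reference implementation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import gammaincc

from .scoring import LanguageSummary, grounding_failure_rate, round_half_up, topn_frequency

#: Rank assigned to non-refusal cases whose differential lacks the correct
#: diagnosis when feeding ranks into the H-test (worst-rank coding; refusals
#: are excluded from the test entirely).
UNRANKED_CODE = 11


class DegenerateDataError(ValueError):
    """All pooled values identical: the tie-corrected H is undefined."""


@dataclass
class KWResult:
    H: float
    p_value: float
    df: int
    tie_corrected: bool
    group_sizes: list[int]


def _midranks(pooled: np.ndarray) -> np.ndarray:
    """Mid-rank assignment (average rank within each tie group), 1-based."""
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled), dtype=float)
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def kruskal_wallis(groups: list[list[float]]) -> KWResult:
    """Tie-corrected Kruskal–Wallis H-test over k groups of ordinal values.

    H = [12/(N(N+1)) * sum(R_j^2/n_j) - 3(N+1)] / C with
    C = 1 - sum(t^3 - t)/(N^3 - N) over tie groups; the p-value is the
    chi-square upper tail with k-1 degrees of freedom.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    sizes = [len(g) for g in groups]
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n_total = len(pooled)
    ranks = _midranks(pooled)

    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - float(np.sum(tie_counts**3 - tie_counts)) / (n_total**3 - n_total)
    if correction == 0.0:
        raise DegenerateDataError("all pooled values are identical; H is undefined")

    h = -3.0 * (n_total + 1)
    offset = 0
    for size in sizes:
        rank_sum = float(np.sum(ranks[offset : offset + size]))
        h += 12.0 / (n_total * (n_total + 1)) * rank_sum**2 / size
        offset += size
    h /= correction
    h = max(h, 0.0)  # guard against tiny negative round-off
    df = len(groups) - 1
    p_value = float(gammaincc(df / 2.0, h / 2.0))
    return KWResult(
        H=h,
        p_value=p_value,
        df=df,
        tie_corrected=bool((tie_counts > 1).any()),
        group_sizes=sizes,
    )


def ranks_for_test(case_scores, unranked_code: int = UNRANKED_CODE) -> list[int]:
    """Per-case rank coding for the H-test: refusals out, unranked -> code."""
    return [
        s.correct_rank if s.correct_rank is not None else unranked_code
        for s in case_scores
        if not s.refusal
    ]


# ---------------------------------------------------------------------------
# Report emission
# ---------------------------------------------------------------------------


def _fmt_p(p: float) -> str:
    return f"{p:.1e}" if p < 1e-3 else f"{p:.4f}"


def counts_table(summaries: list[LanguageSummary], fold_beyond10: bool = True) -> list[dict]:
    rows = []
    for s in summaries:
        not_ranked = s.not_ranked + (s.beyond10 if fold_beyond10 else 0)
        rows.append(
            {
                "language": s.language,
                "top1": s.top1,
                "top3": s.top3,
                "top10": s.top10,
                "not_ranked": not_ranked,
                "no_diagnosis": s.no_diagnosis,
            }
        )
    return rows


def frequency_table(summaries: list[LanguageSummary]) -> list[dict]:
    rows = []
    for s in summaries:
        row: dict = {"language": s.language}
        for n in (1, 3, 10):
            row[f"top{n}_pct"] = topn_frequency(s, n, "exclude_refusals")
            row[f"top{n}_pct_all"] = topn_frequency(s, n, "all")
        rows.append(row)
    return rows


def _write_tsv(rows: list[dict], path: Path) -> None:
    columns = list(rows[0])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in columns) + "\n")


def _write_markdown(rows: list[dict], path: Path) -> None:
    columns = list(rows[0])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("| " + " | ".join(columns) + " |\n")
        fh.write("|" + "|".join(["---"] * len(columns)) + "|\n")
        for row in rows:
            fh.write("| " + " | ".join(str(row[c]) for c in columns) + " |\n")


def emit_report(
    summaries: list[LanguageSummary],
    kw: KWResult | None = None,
    format: str = "tsv",
    out_dir=".",
    failure_rates: dict[str, float] | None = None,
) -> dict[str, Path]:
    """Write the count table, the frequency table (both denominator
    conventions), an optional grounding-failure-rate table, an optional
    H-test block, and a JSON bundle of everything.  Byte-stable for
    identical inputs."""
    if not summaries:
        raise ValueError("no summaries to report")
    if format not in ("tsv", "markdown"):
        raise ValueError(f"unknown format {format!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    writer = _write_tsv if format == "tsv" else _write_markdown
    ext = "tsv" if format == "tsv" else "md"

    paths: dict[str, Path] = {}
    counts = counts_table(summaries)
    paths["counts"] = out_dir / f"counts.{ext}"
    writer(counts, paths["counts"])

    freqs = frequency_table(summaries)
    paths["frequencies"] = out_dir / f"frequencies.{ext}"
    writer(freqs, paths["frequencies"])

    bundle: dict = {"counts": counts, "frequencies": freqs}

    if failure_rates is not None:
        rate_rows = [
            {"language": lang, "grounding_failure_pct": round_half_up(100 * rate, 1)}
            for lang, rate in sorted(failure_rates.items())
        ]
        paths["grounding_failures"] = out_dir / f"grounding_failures.{ext}"
        writer(rate_rows, paths["grounding_failures"])
        bundle["grounding_failures"] = rate_rows

    if kw is not None and len(summaries) > 1:
        kw_text = (
            f"Kruskal-Wallis H = {round_half_up(kw.H, 1)}, "
            f"p = {_fmt_p(kw.p_value)}, df = {kw.df}, "
            f"groups = {kw.group_sizes}\n"
        )
        paths["kruskal_wallis"] = out_dir / "kruskal_wallis.txt"
        paths["kruskal_wallis"].write_text(kw_text, encoding="utf-8")
        bundle["kruskal_wallis"] = {
            "H": kw.H,
            "p_value": kw.p_value,
            "df": kw.df,
            "tie_corrected": kw.tie_corrected,
            "group_sizes": kw.group_sizes,
        }

    paths["bundle"] = out_dir / "report.json"
    with open(paths["bundle"], "w", encoding="utf-8") as fh:
        json.dump(bundle, fh, indent=1, sort_keys=True)
    return paths


def read_counts_tsv(path) -> list[LanguageSummary]:
    """Re-parse an emitted (or shipped) count table into summaries."""
    summaries = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            if not line.strip():
                continue
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            top10 = int(row["top10"])
            not_ranked = int(row["not_ranked"])
            no_diagnosis = int(row.get("no_diagnosis", 0))
            summaries.append(
                LanguageSummary(
                    language=row["language"],
                    n_total=top10 + not_ranked + no_diagnosis,
                    top1=int(row["top1"]),
                    top3=int(row["top3"]),
                    top10=top10,
                    beyond10=0,
                    not_ranked=not_ranked,
                    no_diagnosis=no_diagnosis,
                )
            )
    return summaries
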