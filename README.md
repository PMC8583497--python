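# medroom-mockup-eval

Analytics for **simulation-based mock-up evaluations** of healthcare rooms.

When a hospital plans or renovates a space such as a medication room,
design teams increasingly have intended end-users *enact realistic work
scenarios* inside a full-scale mock-up (physical or virtual) while
behavioural data are collected. This package implements the automated
side of that evaluation for human-factors practitioners and
facility-design researchers:

* **Link analysis** — movement paths layered onto the floor plan as a
  dwell-time occupancy grid, with high-traffic cells flagged.
* **Bumps** — unintended physical contacts between entities (people
  and/or equipment), debounced, as a congestion indicator.
* **Impediments** — a travelled path between two objects that is *more
  than 20% and at least 1 m* longer than necessary because a person or
  movable object had to be circumvented, attributed to the intruding
  entity; also filtered by subtask (e.g. accessing the sharps container).
* **Interruptions** — annotation-coded diversions of attention during an
  open task.
* **Task completion times** — room entry to room exit per enacted role.
* **Layout comparison** — the same measures tabulated for an existing vs
  a proposed layout.
* **Evaluation of the evaluation** — predictive-validity percent
  differences between observed and simulated task times, Likert survey
  summaries with Welch t-tests, and Phillips-style return on investment
  (ROI).

Because real trajectory data from such studies are rarely deposited, the
package ships a **scenario simulator**: scripted agents enter through a
doorway, walk visibility-graph shortest paths between task targets,
dwell, get interrupted, and detour around planted carts. The simulator
records ground truth (planted detours, contacts, interruptions) so every
detector can be tested for exact recovery.

## The core statistics

For a leg with walked length $L_{\text{act}}$ and shortest feasible
baseline length $L_{\text{base}}$ (visibility-graph shortest path among
walls and fixed furniture, inflated by the body radius $r$):

$$\text{impediment} \iff \frac{L_{\text{act}}}{L_{\text{base}}} > 1.2
\;\wedge\; L_{\text{act}} - L_{\text{base}} \ge 1\,\text{m}
\;\wedge\; \text{(a person/movable object intruded the baseline corridor)}$$

where the corridor is the baseline dilated by $2r$.

Predictive validity of simulated task times against observed
(post-occupancy) times $t_{\text{obs}}$:

$$\Delta\% = \operatorname{round}\!\Big(100\,
\frac{t_{\text{sim}} - t_{\text{obs}}}{t_{\text{obs}}}\Big),$$

summarized by the mean and sample SD of the rounded percents.

Return on investment (Phillips convention, most conservative benefit):

$$\text{ROI}\,(\%) = \frac{\text{benefits} - \text{costs}}{\text{costs}}
\times 100 .$$

## Worked example

ROI for a mock-up evaluation with a stated total cost of CAD 99,016 that
avoids a minor renovation (CAD 75,000–100,000 per room) of eight
identical rooms, using the conservative per-room estimate:

```bash
mockupeval roi --hard-costs 84838 --labor-hours 152 --hourly-rate 72.87 \
  --overhead-rate 20 --n-rooms 8 --per-room-cost-low 75000 \
  --per-room-cost-high 100000 --total-cost-override 99016
```

prints

```json
{
  "project_costs": 99016.0,
  "project_benefits": 600000.0,
  "roi_percent": 505.9626726993617,
  "roi_percent_rounded": 506
}
```

i.e. every dollar invested in the evaluation returns CAD 5.06 beyond the
investment itself.

End-to-end pipeline on the bundled fixtures (two medication-room layouts
× four scenarios, seeded):

```bash
mockupeval demo --out demo_out --seed 1
```

writes trajectory logs, per-scenario measure reports, occupancy heatmaps
and a layout comparison. For the four-role scenario this run prints, in
`demo_out/comparison.json`:

| measure | existing | proposed |
|---|---|---|
| interruptions (occurrences) | 2 | 2 |
| bumps (occurrences) | 2 | 4 |
| impediments (occurrences) | 2 | 2 |
| impediments while accessing patient bins | 2 | 0 |
| cart placement | *not programmed* | — |
| searching behaviours | *not possible* | — |

Consolidating the patient bins in the proposed layout removes the
bin-access impediments — the kind of anticipated-outcome check these
evaluations exist to make. Rows marked *not programmed* / *not possible*
document measures that an automated collection pipeline did not or could
not capture; they carry no numbers by design.

In Python:

```python
from mockupeval import AnalysisConfig, compute_measures, generate_scenario
from mockupeval.fixtures import existing_layout, demo_script

layout = existing_layout()
log, truth = generate_scenario(demo_script(4), layout, AnalysisConfig(), seed=1)
report = compute_measures(log, layout)
print(report.summary())
```

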