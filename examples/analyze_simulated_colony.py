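"""Simulate four days of entrance traffic and run the full analysis.

Generates a synthetic detection log for one colony, segments it into events,
classifies them, extracts foraging trips and prints the colony report.
"""

from hivegate import TrafficScenario, build_report, extract_trips, segment
from hivegate.simulate import simulate_traffic

scenario = TrafficScenario(seed=42)
detections, truth = simulate_traffic(scenario)
events = segment(detections)
trips = extract_trips(events)
report = build_report(detections, events, trips, colony_label="worker05")

print(report.to_text())
print(
    f"Simulated ground truth held {len(truth.excursions)} true excursions; "
    f"{report.n_trips} were recovered as trips (cleansing flights shorter "
    "than the 60-s grouping window are unresolvable by design, and imperfect "
    "per-frame detection loses some of the rest)."
)
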