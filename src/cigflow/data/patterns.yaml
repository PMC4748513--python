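# Workflow control-pattern catalogue for the clinical-guideline domain.
#
# One entry per pattern #1..#43 of the Russell / van der Aalst control-flow
# pattern catalogue.  `suitability` records whether the task structure the
# pattern embodies has a counterpart in clinical practice guideline texts
# ("yes"), was dismissed on principled grounds ("no"), or was not found in the
# guideline sample but cannot be ruled out ("unknown").  Patterns labelled
# "yes" or "unknown" are the *relevant* set selected for implementation.
#
# For relevant patterns, `asbru` / `proforma` give the implementability label
# in each target guideline language: direct (dedicated construct),
# workaround (indirect encoding via additional variables), or
# not_implementable (the language cannot express the pattern's rationale).
version: 1
patterns:
  - {id: 1,  name: "Sequence",                                suitability: "yes", note: ""}
  - {id: 2,  name: "Parallel split (AND split)",              suitability: "yes", note: ""}
  - {id: 3,  name: "Synchronization (AND join)",              suitability: "yes", note: "explicit/implicit in a sequencing after a parallel split"}
  - {id: 4,  name: "Exclusive choice (XOR split)",            suitability: "yes", note: ""}
  - {id: 5,  name: "Simple merge (XOR join)",                 suitability: "yes", note: "explicit/implicit in a sequencing after an exclusive choice"}
  - {id: 6,  name: "Multi-choice (OR split)",                 suitability: "yes", note: ""}
  - {id: 7,  name: "Structured synchronizing merge (OR join)", suitability: "yes", note: "explicit/implicit in a sequencing after a multi-choice"}
  - {id: 8,  name: "Multi-merge",                             suitability: "no",  note: "multiple activation of a task only in structured loops"}
  - {id: 9,  name: "Structured discriminator",                suitability: "unknown", note: "synchronization of 2 or more branches waiting for the first incoming branch has not been found in guidelines"}
  - {id: 10, name: "Arbitrary cycles",                        suitability: "no",  note: "multiple activation of a task only in structured loops"}
  - {id: 11, name: "Implicit termination",                    suitability: "yes", note: "by definition"}
  - {id: 12, name: "MIs without synchronization",             suitability: "no",  note: "no multiple, concurrent instances of a task"}
  - {id: 13, name: "MIs with a priori design-time knowledge", suitability: "no",  note: "no multiple, concurrent instances of a task"}
  - {id: 14, name: "MIs with a priori run-time knowledge",    suitability: "no",  note: "no multiple, concurrent instances of a task"}
  - {id: 15, name: "MIs without a priori run-time knowledge", suitability: "no",  note: "no multiple, concurrent instances of a task"}
  - {id: 16, name: "Deferred choice",                         suitability: "yes", note: ""}
  - {id: 17, name: "Interleaved parallel routing",            suitability: "unknown", note: "interleaved routing with the possibility of adding partial ordering constraints has not been found in sample guidelines"}
  - {id: 18, name: "Milestone (deadline)",                    suitability: "yes", note: "WITH or WITHOUT activity disablement beyond the milestone"}
  - {id: 19, name: "Cancel activity",                         suitability: "yes", note: ""}
  - {id: 20, name: "Cancel case",                             suitability: "yes", note: ""}
  - {id: 21, name: "Structured loop",                         suitability: "yes", note: "typically in follow-up activities"}
  - {id: 22, name: "Recursion",                               suitability: "no",  note: "multiple activation of a task only in structured loops"}
  - {id: 23, name: "Transient trigger",                       suitability: "yes", note: "interpreted as triggers to be acted on immediately"}
  - {id: 24, name: "Persistent trigger",                      suitability: "yes", note: "interpreted as triggers to be acted on either immediately or at some future time"}
  - {id: 25, name: "Cancel region",                           suitability: "yes", note: ""}
  - {id: 26, name: "Cancel MI activity",                      suitability: "no",  note: "no multiple, concurrent instances of a task"}
  - {id: 27, name: "Complete MI activity",                    suitability: "no",  note: "no multiple, concurrent instances of a task"}
  - {id: 28, name: "Blocking discriminator",                  suitability: "no",  note: "no multiple execution threads"}
  - {id: 29, name: "Cancelling discriminator",                suitability: "no",  note: "no concurrent execution of tasks within cancelation"}
  - {id: 30, name: "Structured partial join",                 suitability: "unknown", note: "synchronization of 2 or more branches waiting for the first N incoming ones has not been found in guidelines"}
  - {id: 31, name: "Blocking partial join",                   suitability: "no",  note: "no multiple execution threads"}
  - {id: 32, name: "Cancelling partial join",                 suitability: "no",  note: "no concurrent execution of tasks with cancelation"}
  - {id: 33, name: "Generalized AND join",                    suitability: "no",  note: "no multiple execution threads"}
  - {id: 34, name: "Static partial join for MIs",             suitability: "no",  note: "no multiple, concurrent instances of a task"}
  - {id: 35, name: "Cancelling partial join for MIs",         suitability: "no",  note: "no multiple, concurrent instances of a task"}
  - {id: 36, name: "Dynamic partial join for MIs",            suitability: "no",  note: "no multiple, concurrent instances of a task"}
  - {id: 37, name: "Acyclic synchronizing merge",             suitability: "no",  note: "useful for non-structured models only"}
  - {id: 38, name: "General synchronizing merge",             suitability: "no",  note: "multiple activation of a task only in structured loops"}
  - {id: 39, name: "Critical section",                        suitability: "yes", note: ""}
  - {id: 40, name: "Interleaved routing",                     suitability: "yes", note: ""}
  - {id: 41, name: "Thread merge",                            suitability: "no",  note: "no multiple execution threads"}
  - {id: 42, name: "Thread split",                            suitability: "no",  note: "no multiple execution threads"}
  - {id: 43, name: "Explicit termination",                    suitability: "yes", note: ""}
implementability:
  - {id: 1,  asbru: direct,     proforma: direct}
  - {id: 2,  asbru: direct,     proforma: direct}
  - {id: 3,  asbru: direct,     proforma: direct}
  # 4 and 5 are presented together as a typical usage scheme; both carry the
  # combined labels.
  - {id: 4,  asbru: direct,     proforma: direct}
  - {id: 5,  asbru: direct,     proforma: direct}
  - {id: 6,  asbru: direct,     proforma: direct}
  - {id: 7,  asbru: direct,     proforma: direct}
  - {id: 9,  asbru: direct,     proforma: direct}
  - {id: 11, asbru: direct,     proforma: direct}
  - {id: 16, asbru: direct,     proforma: direct}
  - {id: 17, asbru: direct,     proforma: not_implementable}
  - {id: 18, asbru: workaround, proforma: direct}
  - {id: 19, asbru: direct,     proforma: direct}
  - {id: 20, asbru: direct,     proforma: direct}
  - {id: 21, asbru: direct,     proforma: direct}
  - {id: 23, asbru: not_implementable, proforma: direct}
  - {id: 24, asbru: workaround, proforma: direct}
  - {id: 25, asbru: workaround, proforma: direct}
  - {id: 30, asbru: direct,     proforma: direct}
  - {id: 39, asbru: direct,     proforma: not_implementable}
  - {id: 40, asbru: direct,     proforma: not_implementable}
  - {id: 43, asbru: direct,     proforma: direct}
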