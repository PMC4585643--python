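"""Task dependency graph: topological ordering and resumable execution.

Pipeline steps form a DAG — tasks as nodes, prerequisite edges pointing at
their dependents. Topological sorting (deterministic, ties broken by task
id) linearizes the graph so a task always follows everything it depends on.

Execution is resumable: a line-oriented status file records every task's
state (waiting | started | finished | error) together with its command, and
is rewritten after every state change. A re-invocation skips tasks already
finished, so a long run interrupted (or aborted on error) continues from
where it stopped. A task starts only when all its prerequisites are
finished; after any failure no new task is launched and dependents stay
waiting. A status file that does not parse is an error — execution never
silently restarts from scratch.
"""

from __future__ import annotations

import os
from concurrent.futures import FIRST_COMPLETED, ThreadPoolExecutor, wait
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

import networkx as nx

__all__ = ["Task", "TaskGraph", "CycleError", "StatusFileError", "topo_order", "run_graph"]

STATUSES = ("waiting", "started", "finished", "error")


class CycleError(ValueError):
    pass


class StatusFileError(ValueError):
    pass


@dataclass
class Task:
    id: str
    command: str = ""
    status: str = "waiting"

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


class TaskGraph:
    """DAG of tasks with dependency edges prerequisite -> dependent."""

    def __init__(self) -> None:
        self._graph = nx.DiGraph()
        self.tasks: dict[str, Task] = {}

    def add_task(self, task_id: str, command: str = "") -> Task:
        if task_id in self.tasks:
            raise ValueError(f"duplicate task id {task_id!r}")
        task = Task(task_id, command)
        self.tasks[task_id] = task
        self._graph.add_node(task_id)
        return task

    def add_dependency(self, prerequisite: str, dependent: str) -> None:
        for tid in (prerequisite, dependent):
            if tid not in self.tasks:
                raise KeyError(f"unknown task {tid!r}")
        self._graph.add_edge(prerequisite, dependent)

    def prerequisites(self, task_id: str) -> list[str]:
        return list(self._graph.predecessors(task_id))

    def dependents(self, task_id: str) -> list[str]:
        return list(self._graph.successors(task_id))

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self._graph.edges)

    def topo_order(self) -> list[str]:
        return topo_order(self)


def topo_order(graph: TaskGraph) -> list[str]:
    """Dependency-respecting order, ties broken lexicographically by id."""
    try:
        return list(nx.lexicographical_topological_sort(graph._graph))
    except nx.NetworkXUnfeasible:
        cycle = nx.find_cycle(graph._graph)
        chain = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[0][0]}"
        raise CycleError(f"dependency cycle: {chain}") from None


# ---------------------------------------------------------------------------
# status persistence


def load_status(path: str | Path) -> dict[str, Task]:
    tasks: dict[str, Task] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise StatusFileError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, got {len(fields)}"
                )
            task_id, status, command = fields
            if status not in STATUSES:
                raise StatusFileError(f"{path}:{lineno}: unknown status {status!r}")
            if task_id in tasks:
                raise StatusFileError(f"{path}:{lineno}: duplicate task {task_id!r}")
            tasks[task_id] = Task(task_id, command, status)
    return tasks


def save_status(tasks: Iterable[Task], path: str | Path) -> None:
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w") as fh:
        for task in tasks:
            fh.write(f"{task.id}\t{task.status}\t{task.command}\n")
    os.replace(tmp, path)


def run_graph(
    graph: TaskGraph,
    executor: Callable[[Task], bool],
    status_path: str | Path,
    max_parallel: int = 1,
) -> dict[str, str]:
    """Execute the graph, persisting status after every state change.

    *executor* runs one task and returns True on success (an exception
    counts as failure). Tasks recorded as finished in a pre-existing status
    file are skipped. Returns the final task_id -> status map.
    """
    if max_parallel < 1:
        raise ValueError("max_parallel must be positive")
    order = topo_order(graph)  # also validates acyclicity

    status_path = Path(status_path)
    if status_path.exists():
        previous = load_status(status_path)
        for task_id, prev in previous.items():
            if task_id in graph.tasks and prev.status == "finished":
                graph.tasks[task_id].status = "finished"
        # an interrupted "started" task re-runs: reset to waiting
        for task in graph.tasks.values():
            if task.status == "started":
                task.status = "waiting"

    def persist() -> None:
        save_status((graph.tasks[tid] for tid in order), status_path)

    persist()
    failed = False
    with ThreadPoolExecutor(max_workers=max_parallel) as pool:
        futures: dict = {}

        def runnable() -> list[str]:
            return [
                tid
                for tid in order
                if graph.tasks[tid].status == "waiting"
                and all(
                    graph.tasks[p].status == "finished"
                    for p in graph.prerequisites(tid)
                )
            ]

        while True:
            if not failed:
                for tid in runnable():
                    if len(futures) >= max_parallel:
                        break
                    task = graph.tasks[tid]
                    task.status = "started"
                    persist()
                    futures[pool.submit(executor, task)] = tid
            if not futures:
                break
            done, _ = wait(futures, return_when=FIRST_COMPLETED)
            for fut in done:
                tid = futures.pop(fut)
                try:
                    ok = fut.result()
                except Exception:
                    ok = False
                graph.tasks[tid].status = "finished" if ok else "error"
                if not ok:
                    failed = True
                persist()
    return {tid: graph.tasks[tid].status for tid in order}
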