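"""Synthetic prescribing cohort and multi-output drug/dosage/frequency
recommender.

The cohort generator draws virtual patients (age, sex, smoking status,
diagnosis, renal/hepatic comorbidity with exact quota, eGFR, weight,
optional background anticoagulant) and assigns each a prescription from
an editable formulary whose codomain is closed over the 10-drug,
14-dosage, 10-frequency vocabularies. Safety logic is rule-based:
contraindication filtering (beta-blockers never dispensed in asthma), a
25-pair anticoagulant interaction screen, and renal dose adjustment

    dose_adjusted = base * min(1, eGFR / 60)

snapped down to the nearest lower (or equal) mg-valued dosage class.

Because labels are deterministic given features, held-out accuracy of the
recommender approaches 1 by design; that ceiling is a property of the
synthetic generator, not of clinical validity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import classification_report
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder, StandardScaler

from pulmodx.features import CLASSES

DRUGS = (
    "Albuterol", "Amoxicillin", "Azithromycin", "Budesonide", "Doxycycline",
    "Fluticasone", "Hypertonic Saline", "Ibuprofen", "Supportive Care Only",
    "Tiotropium",
)
DOSAGES = (
    "0.5 mg", "0.63-1.25 mg", "1 puff (18 mcg)", "10 mg/kg", "100 mg",
    "2 puffs", "250 mg", "4 mL of 7% saline", "400 mg", "400-600 mg",
    "500 mg", "88 mcg", "90 mg/kg/day", "N/A",
)
FREQUENCIES = (
    "3 to 4 times", "Divided in 2 doses", "Every 4 to 6 h (PRN)",
    "Every 6 to 8 h (PRN)", "Every 8 h", "N/A", "Once daily",
    "Once daily for 3-5 days", "Twice daily", "Twice daily for 7-14 days",
)

#: drugs whose plain-mg doses are scaled by renal function
RENALLY_CLEARED = ("Amoxicillin", "Azithromycin")

#: point-valued mg dosage classes eligible as renal snap targets
MG_CLASSES = {"0.5 mg": 0.5, "100 mg": 100.0, "250 mg": 250.0,
              "400 mg": 400.0, "500 mg": 500.0}

TARGETS = ("drug", "dosage", "frequency")
NUMERIC_FEATURES = ("age", "eGFR", "weight")
CATEGORICAL_FEATURES = ("sex", "smoking", "diagnosis", "renal_impaired",
                        "hepatic_impaired", "background_med")

EGFR_THRESHOLD = 60.0


@dataclass
class PatientRecord:
    id: str
    age: int
    sex: str
    smoking: str
    diagnosis: str
    renal_impaired: bool
    hepatic_impaired: bool
    eGFR: float
    weight: float
    background_med: str = "none"

    def __post_init__(self):
        if not 1 <= self.age <= 95:
            raise ValueError("age must be in [1, 95]")
        if self.eGFR <= 0:
            raise ValueError("eGFR must be positive")
        if self.renal_impaired != (self.eGFR < EGFR_THRESHOLD):
            raise ValueError("renal_impaired flag inconsistent with eGFR")

    @property
    def comorbid(self) -> bool:
        return self.renal_impaired or self.hepatic_impaired


@dataclass(frozen=True)
class Prescription:
    drug: str
    dosage: str
    frequency: str

    def __post_init__(self):
        if self.drug not in DRUGS:
            raise ValueError(f"drug {self.drug!r} not in vocabulary")
        if self.dosage not in DOSAGES:
            raise ValueError(f"dosage {self.dosage!r} not in vocabulary")
        if self.frequency not in FREQUENCIES:
            raise ValueError(f"frequency {self.frequency!r} not in vocabulary")
        if (self.drug == "Supportive Care Only") != (self.dosage == "N/A"):
            raise ValueError("Supportive Care Only pairs with dosage N/A")
        if (self.drug == "Supportive Care Only") != (self.frequency == "N/A"):
            raise ValueError("Supportive Care Only pairs with frequency N/A")


#: Default diagnosis prevalence: respiratory-burden weighted; every
#: formulary drug reaches non-zero support at n = 2000.
DEFAULT_PREVALENCE = {
    "COPD": 0.30, "asthma": 0.20, "URTI": 0.15, "pneumonia": 0.12,
    "healthy": 0.10, "bronchiolitis": 0.06, "bronchiectasis": 0.04,
    "LRTI": 0.03,
}


@dataclass
class CohortConfig:
    n: int = 2000
    comorbidity_rate: float = 0.15
    prevalence: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PREVALENCE))
    seed: int = 0
    anticoagulant_rate: float = 0.08
    label_noise: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.comorbidity_rate <= 1.0:
            raise ValueError("comorbidity_rate must be in [0, 1]")
        total = sum(self.prevalence.values())
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            raise ValueError(f"prevalence sums to {total}, expected 1")
        if set(self.prevalence) - set(CLASSES):
            raise ValueError("prevalence names unknown diagnosis classes")


@dataclass
class RecommenderConfig:
    trees: int = 500
    criterion: str = "gini"
    max_depth: int = 15
    min_samples_leaf: int = 2


ANTICOAGULANTS = ("Warfarin", "Apixaban", "Rivaroxaban", "Dabigatran", "Edoxaban")


def generate_cohort(config: CohortConfig | None = None) -> list[PatientRecord]:
    """Generate exactly ``n`` virtual patients; the comorbidity share is
    quota-sampled so round(n * rate) records carry an impairment flag."""
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n
    diagnoses = rng.choice(list(config.prevalence), size=n,
                           p=list(config.prevalence.values()))
    ages = rng.integers(1, 96, size=n)
    sexes = rng.choice(["female", "male"], size=n)
    smoking_choices = rng.choice(["never", "former", "current"], size=n,
                                 p=[0.5, 0.25, 0.25])
    n_comorbid = round(n * config.comorbidity_rate)
    comorbid_idx = set(rng.choice(n, size=n_comorbid, replace=False).tolist())

    records = []
    for i in range(n):
        age = int(ages[i])
        smoking = "never" if age < 18 else str(smoking_choices[i])
        renal = hepatic = False
        if i in comorbid_idx:
            renal = rng.random() < 0.6
            hepatic = rng.random() < 0.5
            if not (renal or hepatic):
                renal = True
        if renal:
            egfr = float(rng.uniform(15.0, 59.0))
        else:
            egfr = float(np.clip(rng.normal(95.0, 15.0), EGFR_THRESHOLD, 150.0))
        if age < 18:
            weight = float(np.clip(3.5 + 2.8 * age + rng.normal(0, 2.0), 4.0, 80.0))
        else:
            weight = float(np.clip(rng.normal(72.0, 12.0), 40.0, 130.0))
        background = "none"
        if age >= 40 and rng.random() < config.anticoagulant_rate:
            background = str(rng.choice(ANTICOAGULANTS))
        records.append(PatientRecord(
            id=f"P{i:05d}", age=age, sex=str(sexes[i]), smoking=smoking,
            diagnosis=str(diagnoses[i]), renal_impaired=renal,
            hepatic_impaired=hepatic, eGFR=egfr, weight=weight,
            background_med=background))
    return records


# ---------------------------------------------------------------------------
# formulary and safety rules


@dataclass(frozen=True)
class FormularyRule:
    drug: str
    dosage: str
    frequency: str
    alternate: "FormularyRule | None" = None
    smoking_current: dict | None = None


class Formulary:
    """Rule table (diagnosis x age band) with contraindication and
    interaction screens."""

    def __init__(self, raw: dict, interactions: dict):
        self.age_bands = {k: tuple(v) for k, v in raw["age_bands"].items()}
        self.contraindicated = {k: set(v) for k, v in
                                raw.get("contraindications", {}).items()}
        self.rules: dict[tuple[str, str], FormularyRule] = {}
        for diagnosis, bands in raw["rules"].items():
            for band, spec_ in bands.items():
                self.rules[(diagnosis, band)] = self._parse_rule(spec_)
        pairs = set()
        for anti in interactions["anticoagulants"]:
            for drug in interactions["interacting_drugs"]:
                pairs.add((drug, anti))
        self.interaction_pairs = pairs

    @staticmethod
    def _parse_rule(spec_: dict) -> FormularyRule:
        alt = spec_.get("alternate")
        return FormularyRule(
            drug=spec_["drug"], dosage=spec_["dosage"], frequency=spec_["frequency"],
            alternate=Formulary._parse_rule(alt) if alt else None,
            smoking_current=spec_.get("smoking_current"))

    def band(self, age: int) -> str:
        for name, (lo, hi) in self.age_bands.items():
            if lo <= age <= hi:
                return name
        raise KeyError(f"no age band covers age {age}")

    def rule_for(self, diagnosis: str, age: int) -> FormularyRule:
        band = self.band(age)
        try:
            return self.rules[(diagnosis, band)]
        except KeyError:
            raise KeyError(
                f"formulary does not cover ({diagnosis!r}, {band!r})") from None


def load_formulary(formulary_path: str | Path | None = None,
                   interactions_path: str | Path | None = None) -> Formulary:
    if formulary_path is None:
        raw = yaml.safe_load(
            resources.files("pulmodx").joinpath("data/formulary.yaml").read_text())
    else:
        raw = yaml.safe_load(Path(formulary_path).read_text())
    if interactions_path is None:
        inter = yaml.safe_load(
            resources.files("pulmodx").joinpath("data/interactions.yaml").read_text())
    else:
        inter = yaml.safe_load(Path(interactions_path).read_text())
    return Formulary(raw, inter)


def adjust_dose(base: float, egfr: float) -> float:
    """Renal pharmacokinetic scaling: base * min(1, eGFR / 60)."""
    if base <= 0 or egfr <= 0:
        raise ValueError("base dose and eGFR must be positive")
    return base * min(1.0, egfr / EGFR_THRESHOLD)


def snap_dosage(value_mg: float) -> str:
    """Largest mg-valued dosage class not exceeding ``value_mg`` (the
    nearest-lower rule); below the smallest class, the smallest is used."""
    eligible = [(v, label) for label, v in MG_CLASSES.items() if v <= value_mg]
    if not eligible:
        return min(MG_CLASSES, key=MG_CLASSES.get)
    return max(eligible)[1]


def assign_prescription(rec: PatientRecord,
                        formulary: Formulary | None = None) -> Prescription:
    """Deterministic rule engine: formulary lookup, smoking override,
    contraindication filter, interaction screen, renal dose adjustment."""
    formulary = formulary or load_formulary()
    rule = formulary.rule_for(rec.diagnosis, rec.age)
    drug, dosage, frequency = rule.drug, rule.dosage, rule.frequency

    if rec.smoking == "current" and rule.smoking_current:
        drug = rule.smoking_current.get("drug", drug)
        dosage = rule.smoking_current.get("dosage", dosage)
        frequency = rule.smoking_current.get("frequency", frequency)

    def blocked(d: str) -> bool:
        if d in formulary.contraindicated.get(rec.diagnosis, set()):
            return True
        return (d, rec.background_med) in formulary.interaction_pairs

    if blocked(drug):
        alt = rule.alternate
        if alt is None or blocked(alt.drug):
            raise ValueError(
                f"no safe drug for {rec.diagnosis!r} patient {rec.id}")
        drug, dosage, frequency = alt.drug, alt.dosage, alt.frequency

    if rec.renal_impaired and drug in RENALLY_CLEARED and dosage in MG_CLASSES:
        dosage = snap_dosage(adjust_dose(MG_CLASSES[dosage], rec.eGFR))
    return Prescription(drug=drug, dosage=dosage, frequency=frequency)


def cohort_frame(records: list[PatientRecord],
                 formulary: Formulary | None = None,
                 label_noise: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Patient features plus assigned (drug, dosage, frequency) targets.

    ``label_noise`` > 0 randomly re-draws that fraction of drug labels to
    emulate real-world disagreement (default off)."""
    formulary = formulary or load_formulary()
    rows = []
    for rec in records:
        p = assign_prescription(rec, formulary)
        rows.append({
            "id": rec.id, "age": rec.age, "sex": rec.sex,
            "smoking": rec.smoking, "diagnosis": rec.diagnosis,
            "renal_impaired": rec.renal_impaired,
            "hepatic_impaired": rec.hepatic_impaired,
            "eGFR": rec.eGFR, "weight": rec.weight,
            "background_med": rec.background_med,
            "drug": p.drug, "dosage": p.dosage, "frequency": p.frequency,
        })
    df = pd.DataFrame(rows)
    if label_noise > 0:
        rng = np.random.default_rng(seed)
        flip = rng.random(len(df)) < label_noise
        df.loc[flip, "drug"] = rng.choice(DRUGS, size=int(flip.sum()))
    # shuffle to eliminate ordering artifacts
    return df.sample(frac=1.0, random_state=seed).reset_index(drop=True)


def split_cohort(df: pd.DataFrame, test_size: float = 0.2, seed: int = 0):
    """80/20 train/test partition, stratified by drug category."""
    return train_test_split(df, test_size=test_size, random_state=seed,
                            stratify=df["drug"])


def oversample_rare(df: pd.DataFrame, threshold: float = 0.05,
                    seed: int = 0) -> pd.DataFrame:
    """SMOTE-style oversampling of rare (diagnosis, drug) pairs for mixed
    feature types: numeric features are interpolated between same-pair
    rows, categorical features (and the three targets) copied from the
    nearer parent. Pairs with a single row are duplicated with age jitter.
    Original rows are returned untouched, synthetic rows appended."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(df)
    target_count = math.ceil(threshold * n)
    numeric = list(NUMERIC_FEATURES)
    synth_rows = []
    for (diagnosis, drug), group in df.groupby(["diagnosis", "drug"], sort=True):
        need = target_count - len(group)
        if need <= 0:
            continue
        g = group.reset_index(drop=True)
        scale = np.maximum(g[numeric].std(ddof=0).to_numpy(), 1e-9)
        for _ in range(need):
            if len(g) == 1:
                row = g.iloc[0].copy()
                row["age"] = int(np.clip(row["age"] + rng.integers(-2, 3), 1, 95))
            else:
                i, j = rng.choice(len(g), size=2, replace=False)
                a, b = g.iloc[i], g.iloc[j]
                lam = rng.random()
                nearer = a if lam < 0.5 else b
                row = nearer.copy()
                for col in numeric:
                    row[col] = (1 - lam) * a[col] + lam * b[col]
                row["age"] = int(round(row["age"]))
            row["renal_impaired"] = bool(row["eGFR"] < EGFR_THRESHOLD)
            row["id"] = f"S{len(synth_rows):05d}"
            synth_rows.append(row)
    if not synth_rows:
        return df.copy()
    return pd.concat([df, pd.DataFrame(synth_rows)], ignore_index=True)


@dataclass
class PrescriptionRecommender:
    pipeline: Pipeline
    config: RecommenderConfig
    classes_: dict[str, np.ndarray]

    def predict(self, df: pd.DataFrame) -> pd.DataFrame:
        pred = self.pipeline.predict(df[list(NUMERIC_FEATURES + CATEGORICAL_FEATURES)])
        return pd.DataFrame(pred, columns=list(TARGETS), index=df.index)

    def predict_proba(self, df: pd.DataFrame) -> dict[str, np.ndarray]:
        probs = self.pipeline.predict_proba(
            df[list(NUMERIC_FEATURES + CATEGORICAL_FEATURES)])
        return dict(zip(TARGETS, probs))

    def confidence(self, df: pd.DataFrame) -> pd.DataFrame:
        """Per-target maximum posterior probability for each row."""
        probs = self.predict_proba(df)
        return pd.DataFrame({t: p.max(axis=1) for t, p in probs.items()},
                            index=df.index)


def train_recommender(train_df: pd.DataFrame,
                      config: RecommenderConfig | None = None,
                      seed: int = 0) -> PrescriptionRecommender:
    """Fit the multi-output ensemble (one forest jointly predicting drug,
    dosage and frequency) on one-hot categoricals and standardized
    numerics."""
    config = config or RecommenderConfig()
    missing = [t for t in TARGETS if t not in train_df.columns]
    if missing:
        raise ValueError(f"missing target columns: {missing}")
    pre = ColumnTransformer([
        ("num", StandardScaler(), list(NUMERIC_FEATURES)),
        ("cat", OneHotEncoder(handle_unknown="ignore"),
         list(CATEGORICAL_FEATURES)),
    ])
    rf = RandomForestClassifier(
        n_estimators=config.trees, criterion=config.criterion,
        max_depth=config.max_depth, min_samples_leaf=config.min_samples_leaf,
        random_state=seed, n_jobs=1)
    pipe = Pipeline([("pre", pre), ("rf", rf)])
    X = train_df[list(NUMERIC_FEATURES + CATEGORICAL_FEATURES)]
    Y = train_df[list(TARGETS)].to_numpy()
    pipe.fit(X, Y)
    classes = dict(zip(TARGETS, pipe.named_steps["rf"].classes_))
    return PrescriptionRecommender(pipeline=pipe, config=config,
                                   classes_=classes)


def evaluate_recommender(model: PrescriptionRecommender,
                         test_df: pd.DataFrame,
                         low_confidence: float = 0.5):
    """Per-target classification reports plus a summary.

    Returns (reports, summary, flagged): ``reports`` maps each target to a
    per-class precision/recall/F1/support table with macro and weighted
    averages; ``flagged`` lists row ids whose maximum posterior for any
    target falls below ``low_confidence``.
    """
    if len(test_df) == 0:
        raise ValueError("empty test set")
    pred = model.predict(test_df)
    reports: dict[str, pd.DataFrame] = {}
    summary: dict[str, float] = {}
    for target in TARGETS:
        rep = classification_report(test_df[target], pred[target],
                                    output_dict=True, zero_division=0)
        acc = rep.pop("accuracy")
        table = pd.DataFrame(rep).T
        table.index.name = target
        reports[target] = table
        summary[f"{target}_accuracy"] = acc
        summary[f"{target}_macro_f1"] = table.loc["macro avg", "f1-score"]
        summary[f"{target}_weighted_f1"] = table.loc["weighted avg", "f1-score"]
    conf = model.confidence(test_df)
    flagged = test_df.loc[(conf < low_confidence).any(axis=1), "id"].tolist()
    return reports, summary, flagged


def audit_safety(df: pd.DataFrame, formulary: Formulary | None = None) -> None:
    """Safety invariants over a generated (or predicted) prescription table:
    no contraindicated (diagnosis, drug) pair; Supportive Care Only always
    pairs with N/A; renal-impaired patients never receive the unadjusted
    mg class of a renally-cleared drug."""
    formulary = formulary or load_formulary()
    for _, row in df.iterrows():
        if row["drug"] in formulary.contraindicated.get(row["diagnosis"], set()):
            raise AssertionError(
                f"contraindicated pair: {row['diagnosis']}/{row['drug']}")
        if (row["drug"] == "Supportive Care Only") != (row["dosage"] == "N/A"):
            raise AssertionError("Supportive Care Only must pair with N/A")
        if (row["drug"] in RENALLY_CLEARED and row["eGFR"] < EGFR_THRESHOLD
                and row["dosage"] in MG_CLASSES):
            rule = formulary.rule_for(row["diagnosis"], int(row["age"]))
            for r in (rule, rule.alternate):
                if r is not None and r.drug == row["drug"] and r.dosage in MG_CLASSES:
                    if MG_CLASSES[row["dosage"]] > adjust_dose(
                            MG_CLASSES[r.dosage], row["eGFR"]):
                        raise AssertionError(
                            f"unadjusted renal dose for {row['id']}")
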