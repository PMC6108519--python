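"""Canonical food groups, eating occasions and reference intake levels.

The 39 aggregated food groups and the four main meals (breakfast, lunch,
afternoon snack, dinner) follow the EPIC-Potsdam 24-hour-recall convention.
``REFERENCE_MEAL_INTAKE`` holds mean +/- SD gram amounts per group and meal
for that cohort; the synthetic-cohort generator calibrates its zero-inflated
margins against these levels.
"""

from __future__ import annotations

FOOD_GROUPS: tuple[str, ...] = (
    "Potatoes",
    "Leafy vegetables",
    "Fruiting & root vegetables",
    "Cabbages",
    "Other vegetables",
    "Legumes",
    "Fresh fruits",
    "Nuts",
    "Other fruits",
    "Milk & dairy products",
    "Cheese",
    "Desserts",
    "Pasta & rice",
    "Bread",
    "Breakfast cereals",
    "Other cereals",
    "Red meat",
    "Poultry",
    "Processed meat",
    "Fish",
    "Eggs",
    "Margarine",
    "Vegetable oils",
    "Butter & animal fat",
    "Sugar & confectionery",
    "Cakes & cookies",
    "Fruit & vegetable juices",
    "Soft drinks",
    "Tea",
    "Coffee",
    "Water",
    "Wine",
    "Beer",
    "Spirits",
    "Other alcoholic beverages",
    "Sauces",
    "Condiments",
    "Soups",
    "Snacks",
)

MAIN_MEALS: tuple[str, ...] = ("breakfast", "lunch", "afternoon snack", "dinner")

# 11 eating occasions per recall day; the four main meals plus smaller
# in-between occasions (labels follow the EPIC-Soft style of occasion coding).
OCCASIONS: tuple[str, ...] = (
    "before breakfast",
    "breakfast",
    "mid-morning snack",
    "late-morning snack",
    "lunch",
    "early-afternoon snack",
    "afternoon snack",
    "late-afternoon snack",
    "dinner",
    "evening snack",
    "night snack",
)

# Mean and SD of gram intake per eating event, by food group, for the four
# main meals, and per day for the habitual average (cohort reference values).
# Tuples are (breakfast, lunch, afternoon snack, dinner, habitual), each
# (mean, sd).
REFERENCE_MEAL_INTAKE: dict[str, tuple[tuple[float, float], ...]] = {
    "Potatoes": ((0.01, 0.40), (72.53, 92.30), (1.48, 16.39), (12.46, 44.80), (81.7, 66.5)),
    "Leafy vegetables": ((0.22, 4.85), (5.62, 25.98), (0.16, 4.51), (5.52, 24.42), (11.6, 22.3)),
    "Fruiting & root vegetables": ((7.58, 30.00), (33.93, 72.49), (2.25, 18.45), (56.17, 84.38), (103.0, 83.7)),
    "Cabbages": ((0.01, 0.61), (17.86, 47.91), (0.41, 7.86), (5.40, 31.11), (22.5, 33.7)),
    "Other vegetables": ((0.32, 4.55), (23.91, 58.39), (0.58, 6.80), (9.74, 34.98), (32.9, 38.6)),
    "Legumes": ((1.22, 14.56), (3.56, 25.37), (0.70, 15.09), (0.96, 10.57), (6.64, 27.2)),
    "Fresh fruits": ((36.73, 72.05), (52.68, 94.40), (19.93, 67.53), (38.41, 93.10), (231.0, 154.0)),
    "Nuts": ((0.69, 4.60), (0.23, 2.64), (0.27, 5.24), (0.24, 2.74), (3.95, 10.2)),
    "Other fruits": ((1.22, 18.03), (3.99, 28.93), (0.72, 14.16), (2.21, 25.07), (10.2, 33.2)),
    "Milk & dairy products": ((58.88, 97.18), (32.37, 75.63), (20.27, 52.55), (26.29, 78.47), (167.0, 153.0)),
    "Cheese": ((13.08, 20.13), (3.28, 12.82), (0.67, 5.92), (18.27, 26.56), (37.4, 27.1)),
    "Desserts": ((0.06, 2.80), (9.23, 39.27), (3.73, 23.74), (1.85, 17.46), (17.6, 33.8)),
    "Pasta & rice": ((0.31, 5.75), (17.84, 55.32), (0.54, 10.86), (4.81, 31.07), (23.1, 39.4)),
    "Bread": ((52.09, 33.41), (10.47, 24.39), (3.51, 13.66), (41.16, 35.54), (113.0, 48.4)),
    "Breakfast cereals": ((2.53, 11.73), (0.26, 3.78), (0.13, 3.06), (0.22, 4.40), (3.40, 12.1)),
    "Other cereals": ((1.27, 7.24), (1.06, 7.49), (0.19, 2.54), (1.31, 10.88), (5.30, 11.9)),
    "Red meat": ((0.89, 10.47), (27.46, 56.58), (1.42, 16.90), (11.19, 39.99), (39.5, 46.3)),
    "Poultry": ((0.18, 4.68), (9.15, 35.84), (0.35, 7.52), (5.67, 29.96), (14.8, 27.4)),
    "Processed meat": ((9.78, 18.12), (20.96, 44.27), (2.32, 15.96), (25.08, 37.36), (60.8, 46.1)),
    "Fish": ((1.69, 10.66), (11.37, 43.05), (0.57, 9.68), (11.25, 40.82), (24.1, 37.9)),
    "Eggs": ((10.16, 24.14), (4.79, 19.53), (0.37, 5.76), (2.98, 15.40), (18.7, 22.3)),
    "Margarine": ((5.20, 9.87), (2.18, 5.94), (0.33, 2.43), (4.95, 9.43), (13.2, 16.9)),
    "Vegetable oils": ((0.22, 2.07), (2.84, 7.33), (0.10, 1.42), (1.98, 6.09), (5.06, 6.36)),
    "Butter & animal fat": ((7.78, 11.32), (3.16, 7.67), (0.50, 3.13), (5.64, 10.99), (17.6, 18.5)),
    "Sugar & confectionery": ((18.96, 22.32), (2.16, 9.11), (3.71, 11.78), (2.06, 8.07), (38.0, 29.7)),
    "Cakes & cookies": ((1.96, 17.19), (4.23, 30.15), (51.31, 72.47), (1.56, 14.50), (59.2, 55.5)),
    "Fruit & vegetable juices": ((14.69, 49.74), (16.14, 56.78), (6.50, 36.50), (14.58, 53.63), (94.5, 144.0)),
    "Soft drinks": ((0.57, 13.16), (7.82, 47.78), (4.17, 35.78), (13.14, 71.60), (48.1, 126.0)),
    "Tea": ((84.94, 172.94), (24.62, 86.50), (34.61, 103.49), (90.52, 157.37), (355.0, 381.0)),
    "Coffee": ((220.36, 170.34), (17.99, 63.07), (152.87, 140.45), (3.59, 31.03), (447.0, 230.0)),
    "Water": ((28.53, 71.62), (92.74, 127.49), (59.84, 121.59), (80.63, 130.08), (740.0, 477.0)),
    "Wine": ((0.45, 10.53), (5.89, 40.38), (3.15, 25.82), (12.10, 56.78), (57.3, 101.0)),
    "Beer": ((0.0, 0.0), (14.76, 78.08), (7.35, 60.70), (56.62, 164.54), (173.0, 316.0)),
    "Spirits": ((0.0, 0.0), (0.02, 0.67), (0.12, 2.08), (0.13, 2.40), (1.59, 6.99)),
    "Other alcoholic beverages": ((0.0, 0.0), (0.65, 12.34), (0.80, 13.99), (0.64, 9.78), (4.99, 20.1)),
    "Sauces": ((0.40, 2.67), (17.26, 37.74), (0.45, 4.69), (6.72, 19.74), (24.2, 25.1)),
    "Condiments": ((0.33, 1.47), (0.91, 3.47), (0.17, 1.46), (1.10, 3.80), (2.79, 4.60)),
    "Soups": ((2.29, 24.40), (36.20, 93.40), (1.51, 19.88), (11.99, 57.41), (51.8, 74.8)),
    "Snacks": ((0.18, 2.66), (0.59, 9.94), (0.12, 2.72), (0.68, 9.12), (1.60, 8.71)),
}

# Ground-truth latent dependence structure per main meal for the synthetic
# cohort: signed food-group pairs reflecting conditional dependencies
# reported for this cohort (e.g. bread eaten with spreads at breakfast;
# tea/coffee substituting for each other; beverage exclusivity at dinner).
MEAL_GRAPH_EDGES: dict[str, tuple[tuple[str, str, int], ...]] = {
    "breakfast": (
        ("Nuts", "Other cereals", +1),
        ("Fresh fruits", "Nuts", +1),
        ("Fresh fruits", "Legumes", +1),
        ("Bread", "Margarine", +1),
        ("Bread", "Butter & animal fat", +1),
        ("Bread", "Sugar & confectionery", +1),
        ("Bread", "Processed meat", +1),
        ("Bread", "Cheese", +1),
        ("Processed meat", "Margarine", +1),
        ("Processed meat", "Sugar & confectionery", -1),
        ("Tea", "Coffee", -1),
        ("Sauces", "Fish", +1),
        ("Sauces", "Other vegetables", +1),
        ("Fruiting & root vegetables", "Other vegetables", +1),
        ("Poultry", "Other vegetables", +1),
        ("Milk & dairy products", "Breakfast cereals", +1),
    ),
    "lunch": (
        ("Other cereals", "Condiments", +1),
        ("Other cereals", "Legumes", +1),
        ("Legumes", "Soups", +1),
        ("Other cereals", "Soups", +1),
        ("Red meat", "Other vegetables", +1),
        ("Margarine", "Vegetable oils", -1),
        ("Other vegetables", "Vegetable oils", +1),
        ("Other cereals", "Other vegetables", +1),
        ("Bread", "Cheese", +1),
        ("Bread", "Potatoes", -1),
        ("Bread", "Pasta & rice", -1),
        ("Potatoes", "Cheese", -1),
        ("Potatoes", "Pasta & rice", -1),
        ("Cabbages", "Potatoes", +1),
        ("Potatoes", "Red meat", +1),
        ("Red meat", "Cabbages", +1),
        ("Red meat", "Sauces", +1),
        ("Butter & animal fat", "Sauces", +1),
        ("Coffee", "Cakes & cookies", +1),
        ("Coffee", "Milk & dairy products", +1),
        ("Coffee", "Sugar & confectionery", +1),
    ),
    "afternoon snack": (
        ("Coffee", "Cakes & cookies", +1),
        ("Cakes & cookies", "Milk & dairy products", +1),
        ("Coffee", "Milk & dairy products", +1),
        ("Water", "Coffee", -1),
        ("Water", "Cakes & cookies", -1),
        ("Cakes & cookies", "Bread", -1),
        ("Bread", "Margarine", +1),
        ("Bread", "Processed meat", +1),
        ("Bread", "Cheese", +1),
        ("Fruiting & root vegetables", "Processed meat", +1),
        ("Fruiting & root vegetables", "Margarine", +1),
        ("Fruiting & root vegetables", "Cheese", +1),
        ("Bread", "Butter & animal fat", +1),
        ("Butter & animal fat", "Cabbages", +1),
        ("Butter & animal fat", "Fruiting & root vegetables", +1),
        ("Potatoes", "Vegetable oils", +1),
        ("Potatoes", "Other vegetables", +1),
        ("Other vegetables", "Fruiting & root vegetables", +1),
        ("Fruiting & root vegetables", "Red meat", +1),
        ("Red meat", "Cabbages", +1),
        ("Cabbages", "Soups", +1),
        ("Soups", "Potatoes", +1),
    ),
    "dinner": (
        ("Bread", "Processed meat", +1),
        ("Bread", "Margarine", +1),
        ("Bread", "Butter & animal fat", +1),
        ("Butter & animal fat", "Margarine", -1),
        ("Potatoes", "Cabbages", +1),
        ("Potatoes", "Red meat", +1),
        ("Potatoes", "Other vegetables", +1),
        ("Beer", "Tea", -1),
        ("Beer", "Water", -1),
        ("Tea", "Water", -1),
        ("Tea", "Sugar & confectionery", +1),
        ("Soups", "Potatoes", +1),
    ),
}
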