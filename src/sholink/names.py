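"""Fixture pools for the synthetic-data generator.

Canonical given names (typical of U.S. birth cohorts 1900-1954), surnames,
a nickname table, and New Jersey-style geography. The canonical pools are
constructed to be mutually dissimilar (pairwise Levenshtein >= 2; given
names also Jaro-Winkler < 0.88 and free of nickname relations), so that two
distinct synthetic persons can never collide into a Medium-or-better name
quality unless an identifier error is injected. A test asserts this
property; edit the pools only if it still holds.

Sampling weights follow a Zipf-like law (weight ~ 1/rank^s) so common
names are genuinely common, as in real registries.
"""

from __future__ import annotations

import numpy as np

# fmt: off
MALE_FIRST = [
    "James", "Robert", "John", "William", "Richard", "Charles", "Donald",
    "George", "Kenneth", "Joseph", "Edward", "Thomas", "Harold", "Paul",
    "Raymond", "Walter", "Henry", "Arthur", "Albert", "Lawrence",
    "Eugene", "Ralph", "Howard", "Carl", "Louis",
    "Norman", "Leonard", "Stanley", "Herbert", "Ernest",
    "Frederick", "Anthony", "Samuel", "Bernard", "Melvin",
    "Vincent", "Leroy", "Gordon", "Lloyd", "Russell", "Theodore",
    "Clifford", "Vernon", "Roland", "Chester", "Herman", "Gilbert",
    "Hugh", "Milton", "Jerome", "Cecil", "Alfred", "Wallace",
    "Victor", "Julius", "Oscar", "Edwin", "Sidney", "Everett", "Wesley",
    "Gerard", "Angelo", "Salvatore", "Dominick", "Pasquale", "Seymour",
    "Irving", "Sheldon", "Murray", "Nathan", "Abraham", "Harvey", "Morris",
    "Stuart", "Benjamin", "Frank", "Philip", "Martin", "Roger", "Bruce",
    "Glenn", "Keith", "Wayne", "Alan", "Neil", "Curtis",
]
FEMALE_FIRST = [
    "Mary", "Dorothy", "Helen", "Margaret", "Ruth", "Virginia", "Doris",
    "Mildred", "Elizabeth", "Evelyn", "Anna", "Marie", "Alice",
    "Jean", "Shirley", "Barbara", "Irene", "Florence",
    "Martha", "Rose", "Lillian", "Catherine",
    "Gladys", "Thelma", "Phyllis", "Juanita",
    "Beatrice", "Gloria", "Lucille", "Eleanor", "Edna", "Hazel", "Esther",
    "Emma", "Grace", "Edith", "Rita", "Wanda", "Audrey",
    "Elaine", "Beverly", "Janet", "Patricia",
    "Nancy", "Sandra", "Judith", "Sharon", "Kathleen", "Linda",
    "Donna", "Brenda", "Diane", "Pamela", "Gail", "Bonnie",
    "Sylvia", "Vivian", "Stella", "Vera", "Pearl", "Agnes", "Blanche",
    "Ethel", "Selma", "Harriet", "Miriam", "Sadie", "Yvonne", "Lorraine",
    "Geraldine", "Regina", "Theresa",
    "Antoinette", "Concetta", "Filomena", "Deborah", "Susan",
]
SURNAMES = [
    "Smith", "Johnson", "Williams", "Brown", "Jones", "Miller", "Davis",
    "Garcia", "Rodriguez", "Wilson", "Martinez", "Anderson", "Taylor",
    "Thomas", "Moore", "Jackson", "Martin", "Lee", "Perez", "Thompson",
    "White", "Harris", "Sanchez", "Clark", "Ramirez", "Lewis", "Robinson",
    "Walker", "Young", "Allen", "King", "Wright", "Scott", "Torres",
    "Nguyen", "Hill", "Flores", "Green", "Adams", "Nelson", "Baker",
    "Rivera", "Campbell", "Mitchell", "Carter", "Roberts",
    "Gomez", "Phillips", "Evans", "Turner", "Diaz", "Parker", "Cruz",
    "Edwards", "Collins", "Reyes", "Stewart", "Morris", "Morales",
    "Murphy", "Cook", "Rogers", "Gutierrez", "Ortiz", "Morgan", "Cooper",
    "Peterson", "Bailey", "Reed", "Kelly", "Howard", "Ramos", "Kim",
    "Cox", "Ward", "Richardson", "Watson", "Brooks", "Chavez", "Wood",
    "Bennett", "Gray", "Mendoza", "Ruiz", "Hughes", "Price", "Alvarez",
    "Castillo", "Sanders", "Patel", "Myers", "Long", "Ross", "Foster",
    "Jimenez", "Powell", "Sullivan", "Russell", "Ortega", "Fisher",
    "McCarthy", "Marino", "Esposito", "Russo", "Ferraro", "Lombardi",
    "DeLuca", "Caruso", "Moretti", "Ricci", "Conti", "Gallagher",
    "OConnor", "Kaplan", "Goldberg", "Rosenberg", "Schwartz", "Friedman",
    "Hoffman", "Schneider", "Wagner", "Becker", "Schulz", "Zimmerman",
    "Kowalski", "Nowak", "Wisniewski", "Jablonski", "Szymanski",
    "Fitzgerald", "Donnelly", "Brennan", "Flanagan", "Callahan",
]
# fmt: on

NICKNAMES: dict[str, list[str]] = {
    "John": ["Jon", "Johnny", "Jack"],
    "Robert": ["Bob", "Rob", "Bobby"],
    "William": ["Bill", "Will", "Billy"],
    "Richard": ["Dick", "Rich", "Ricky"],
    "James": ["Jim", "Jimmy", "Jamie"],
    "Charles": ["Chuck", "Charlie"],
    "Joseph": ["Joe", "Joey"],
    "Thomas": ["Tom", "Tommy"],
    "Donald": ["Don", "Donnie"],
    "Kenneth": ["Ken", "Kenny"],
    "Edward": ["Ed", "Eddie", "Ted"],
    "Raymond": ["Ray"],
    "Lawrence": ["Larry"],
    "Ronald": ["Ron", "Ronnie"],
    "Gerald": ["Jerry"],
    "Leonard": ["Len", "Lenny"],
    "Albert": ["Al"],
    "Herbert": ["Herb"],
    "Francis": ["Fran", "Frank"],
    "Frederick": ["Fred", "Freddie"],
    "Anthony": ["Tony"],
    "Samuel": ["Sam", "Sammy"],
    "Bernard": ["Bernie"],
    "Vincent": ["Vince", "Vinny"],
    "Theodore": ["Ted", "Teddy"],
    "Benjamin": ["Ben", "Benny"],
    "Abraham": ["Abe"],
    "Nathan": ["Nate"],
    "Philip": ["Phil"],
    "Martin": ["Marty"],
    "Eugene": ["Gene"],
    "Walter": ["Walt", "Wally"],
    "Harold": ["Hal", "Harry"],
    "Stanley": ["Stan"],
    "Salvatore": ["Sal"],
    "Dominick": ["Dom", "Nick"],
    "Margaret": ["Peggy", "Meg", "Maggie", "Marge"],
    "Elizabeth": ["Liz", "Beth", "Betty", "Betsy"],
    "Dorothy": ["Dot", "Dottie"],
    "Mildred": ["Millie"],
    "Frances": ["Fran", "Frannie"],
    "Virginia": ["Ginny"],
    "Barbara": ["Barb", "Bobbie"],
    "Katherine": ["Kate", "Kathy", "Kitty"],
    "Catherine": ["Cathy", "Kate"],
    "Kathleen": ["Kathy", "Katie"],
    "Patricia": ["Pat", "Patty", "Trish"],
    "Josephine": ["Jo", "Josie"],
    "Lucille": ["Lucy"],
    "Florence": ["Flo", "Flossie"],
    "Beatrice": ["Bea"],
    "Gertrude": ["Trudy"],
    "Harriet": ["Hattie"],
    "Lillian": ["Lil", "Lily"],
    "Pamela": ["Pam"],
    "Deborah": ["Debbie", "Deb"],
    "Susan": ["Sue", "Susie"],
    "Sandra": ["Sandy"],
    "Judith": ["Judy"],
    "Rebecca": ["Becky"],
    "Eleanor": ["Ellie", "Nell"],
    "Geraldine": ["Geri"],
    "Jacqueline": ["Jackie"],
    "Antoinette": ["Toni"],
    "Concetta": ["Connie"],
    "Theresa": ["Terry", "Tess"],
    "Rosemarie": ["Rose", "Romy"],
}

#: Race/ethnicity levels and sampling weights for the beneficiary summary file
#: (shares typical of the New Jersey Medicare population).
RACE_ETHNICITY = [
    ("Non-Hispanic White", 0.7972),
    ("Black (or African American)", 0.0704),
    ("Hispanic", 0.0534),
    ("Asian/Pacific Islander", 0.0430),
    ("Unknown", 0.0246),
    ("Other", 0.0111),
    ("American Indian/Alaskan Native", 0.0003),
]

#: ZIP pools by state. New Jersey ZIPs span 07001-08989; a handful of
#: out-of-state pools cover moves out of NJ.
_rng = np.random.default_rng(20190101)
NJ_ZIPS = sorted(
    {f"{z:05d}" for z in _rng.choice(np.arange(7001, 8990), size=420, replace=False)}
)
STATE_ZIPS = {
    "NJ": NJ_ZIPS,
    "PA": [f"{z:05d}" for z in range(19010, 19160, 3)],
    "NY": [f"{z:05d}" for z in range(10001, 10300, 6)],
    "DE": [f"{z:05d}" for z in range(19701, 19981, 7)],
    "FL": [f"{z:05d}" for z in range(33101, 33400, 6)],
}
del _rng
OUT_OF_STATE = ["PA", "NY", "DE", "FL"]

CITATION_TYPES = ["speeding", "failure_to_yield", "careless_driving", "red_light", "improper_turn"]
SUSPENSION_TYPES = ["basic_driving_privilege", "registration_privilege", "all_privileges"]

CONDITIONS = {
    "cataracts": 0.5583,
    "chronic_pain_fatigue_fibromyalgia": 0.3064,
    "glaucoma": 0.2398,
    "hearing_impairment": 0.1493,
    "alzheimers_dementia": 0.1212,
    "epilepsy": 0.0245,
}


def zipf_weights(n: int, s: float = 0.9) -> np.ndarray:
    """Normalized Zipf-like weights for ranks 1..n (weight ~ 1/rank^s)."""
    w = 1.0 / np.arange(1, n + 1, dtype=float) ** s
    return w / w.sum()


def nickname_pairs(table: dict[str, list[str]] | None = None) -> set[frozenset[str]]:
    """Unordered canonical-form pairs related through the nickname table.

    Includes canonical<->variant pairs and variant<->variant pairs that
    share a canonical name (Betty and Liz are both Elizabeth).
    """
    from .textcomp import canonicalize_name

    table = NICKNAMES if table is None else table
    pairs: set[frozenset[str]] = set()
    for canon, variants in table.items():
        group = [canonicalize_name(canon)] + [canonicalize_name(v) for v in variants]
        for i, a in enumerate(group):
            for b in group[i + 1 :]:
                if a != b:
                    pairs.add(frozenset((a, b)))
    return pairs
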