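import pytest

from pharmstock import InventoryDataset, ProductRecord, SyntheticConfig, generate_ledger


@pytest.fixture
def small_dataset() -> InventoryDataset:
    """Three hand-written products covering both sectors and optional fields."""
    return InventoryDataset(
        [
            ProductRecord(
                product_id="P001",
                product_name="amoxicillin 500mg",
                assortment_class="prescription_medicine",
                qty_purchased=1200,
                qty_dispensed=1100,
                purchase_value=3400.0,
                sales_revenue=3900.0,
                service_fee_revenue=55.0,
                opening_balance=300.0,
                closing_balance=260.0,
            ),
            ProductRecord(
                product_id="P002",
                product_name="chamomile tea",
                assortment_class="tea",
                qty_purchased=80,
                qty_dispensed=60,
                purchase_value=120.0,
                gross_profit=-15.0,  # loss-leader, precomputed
                opening_balance=30.0,
                closing_balance=25.0,
            ),
            ProductRecord(
                product_id="P003",
                product_name="vitamin D drops",
                assortment_class="dietary_supplement",
                qty_purchased=500,
                qty_dispensed=480,
                purchase_value=900.0,
                sales_revenue=1300.0,
            ),
        ]
    )


@pytest.fixture
def synthetic_ledger() -> InventoryDataset:
    """A mid-sized seeded ledger for aggregate checks."""
    return generate_ledger(SyntheticConfig(n_products=500, seed=42))
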